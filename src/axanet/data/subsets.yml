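# Named taxon subsets used by the analysis pipeline.
#
# Membership is resolved against a concrete matrix by genus-name prefixes
# (plus explicit includes/excludes), so the lists survive minor label
# spelling differences between matrix editions.  These lists are
# reconstructed from the published classification; users can supply their
# own file with the same layout.

outgroup:
  prefixes: [Grammatopteris, Grammatocaulis, Rastropteris]
  notes: "Non-member reference taxa."

guaireaceae:
  prefixes: [Guairea, Lunea, Zhongmingella, Itopsidema, Donwelliacaulis, Tiania]
  notes: "Both subfamilies of the extinct family."

osmundaceae:
  prefixes: [
    Thamnopteris, Chasmatopteris, Zalesskya, Iegosigopteris, Petcheropteris,
    Palaeosmunda, Millerocaulis, Ashicaulis,
    Todea, Leptopteris,
    Claytosmunda, Osmundastrum, Osmunda, Plenasium, Aurealcaulis, Australosmunda,
    Osmundacaulis, Shuichengella, Anomorrhoea, Bathypteris,
  ]
  notes: >
    Family-level subset including the genera of uncertain subfamily
    placement.  'Osmunda' also prefixes 'Osmundastrum'/'Osmundacaulis';
    prefix resolution is by union so this is harmless here.

thamnopteroideae:
  prefixes: [Thamnopteris, Chasmatopteris, Zalesskya, Iegosigopteris,
             Petcheropteris, Bathypteris]
  notes: >
    Subfamily subset; includes the incertae-sedis Bathypteris as in the
    published subset analysis, plus labels under the genus names that were
    synonymized into Thamnopteris.

osmundoideae:
  prefixes: [
    Palaeosmunda, Millerocaulis, Ashicaulis,
    Todea, Leptopteris,
    Claytosmunda, Osmundastrum, Osmunda, Plenasium, Aurealcaulis, Australosmunda,
  ]
  exclude: [Osmundacaulis]
  notes: "Subfamily subset: Palaeosmunda + Millerocaulis + the modern tribe."

millerocaulis:
  prefixes: [Millerocaulis, Ashicaulis]
  exclude: [Millerocaulis stipabonettiorum]
  notes: >
    Genus-only subset.  M. stipabonettiorum is excluded (treated as a
    possible Palaeosmunda).

osmundeae:
  prefixes: [Todea, Leptopteris, Claytosmunda, Osmundastrum, Osmunda,
             Plenasium, Aurealcaulis, Australosmunda]
  exclude: [Osmundacaulis, Osmundites]
  notes: "Tribe of genera with extant species, plus their fossil members."

todeinae:
  prefixes: [Todea, Leptopteris]
  notes: "Subtribe subset."

osmundinae:
  prefixes: [Claytosmunda, Osmundastrum, Osmunda, Plenasium, Aurealcaulis,
             Australosmunda]
  exclude: [Osmundacaulis, Osmundites]
  notes: "Subtribe subset."

osmundacaulis:
  prefixes: [Osmundacaulis]
  notes: "Genus of uncertain subfamily placement."
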