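"""Readers and writers for the plain-text formats the pipeline touches.

Supported:

* NEXUS ``DATA``/``CHARACTERS`` blocks for categorical character matrices
  (missing ``?``, gap ``-`` both mapped to missing; ``(..)``/``{..}``
  multistate entries mapped to ambiguity sets; interleaved input tolerated).
* NEXUS ``DISTANCES`` blocks and square PHYLIP distance matrices.
* SplitsTree-compatible ``SPLITS`` blocks (``CYCLE`` + ``MATRIX``) so that
  inferred split systems load directly in a splits-graph viewer.

The gap symbol is deliberately treated as missing data: the downstream
analysis distinguishes only defined versus undefined cells.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import numpy as np

from .matrix import (
    CellValue,
    CharacterDefinition,
    CharacterMatrix,
    DistanceMatrix,
    ValidationError,
)
from .splits import CircularOrdering, Split, SplitSystem

__all__ = [
    "ParseError",
    "read_nexus_matrix",
    "write_nexus_matrix",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_splits_nexus",
    "write_splits_nexus",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


# ---------------------------------------------------------------------------
# low-level NEXUS scaffolding
# ---------------------------------------------------------------------------


def _strip_comments(text: str) -> str:
    """Remove bracketed NEXUS comments, preserving newlines for line counts."""
    out: list[str] = []
    depth = 0
    for ch in text:
        if ch == "[":
            depth += 1
        elif ch == "]":
            if depth > 0:
                depth -= 1
            else:
                out.append(ch)
        elif depth == 0 or ch == "\n":
            out.append(ch)
    return "".join(out)


def _commands(block_text: str, start_line: int) -> list[tuple[str, int]]:
    """Split block text into ';'-terminated commands with line numbers."""
    cmds: list[tuple[str, int]] = []
    buf: list[str] = []
    line = start_line
    cmd_line = start_line
    in_quote = False
    for ch in block_text:
        if ch == "'":
            in_quote = not in_quote
        if ch == "\n":
            line += 1
        if ch == ";" and not in_quote:
            text = "".join(buf).strip()
            if text:
                cmds.append((text, cmd_line))
            buf = []
            cmd_line = line
        else:
            if not buf and ch.strip():
                cmd_line = line
            buf.append(ch)
    tail = "".join(buf).strip()
    if tail:
        cmds.append((tail, cmd_line))
    return cmds


def _find_blocks(text: str) -> list[tuple[str, str, int]]:
    """Return (block_name_lower, body_text, start_line) for each NEXUS block."""
    blocks = []
    pattern = re.compile(r"begin\s+(\w+)\s*;", re.IGNORECASE)
    pos = 0
    while True:
        m = pattern.search(text, pos)
        if not m:
            break
        name = m.group(1).lower()
        end = re.compile(r"end\s*(?:;|$)", re.IGNORECASE).search(text, m.end())
        if end is None:
            line = text.count("\n", 0, m.start()) + 1
            raise ParseError(f"block {name!r} is never closed with END;", line)
        body = text[m.end() : end.start()]
        start_line = text.count("\n", 0, m.end()) + 1
        blocks.append((name, body, start_line))
        pos = end.end()
    return blocks


def _parse_keyvals(command: str) -> dict[str, str]:
    """Parse 'KEY=VALUE KEY2=VALUE2 FLAG' payloads (values may be quoted)."""
    out: dict[str, str] = {}
    for m in re.finditer(r"(\w+)\s*=\s*(\"[^\"]*\"|'[^']*'|\S+)|(\w+)", command):
        if m.group(1):
            out[m.group(1).lower()] = m.group(2).strip("\"'")
        elif m.group(3):
            out[m.group(3).lower()] = ""
    return out


_LABEL_RE = re.compile(r"'([^']*)'|(\S+)")


def _normalize_label(raw: str, quoted: bool) -> str:
    if quoted:
        return " ".join(raw.split())
    return " ".join(raw.replace("_", " ").split())


def _quote_label(label: str) -> str:
    if re.fullmatch(r"[\w.\-]+", label):
        return label
    if " " in label and re.fullmatch(r"[\w.\- ]+", label):
        return label.replace(" ", "_")
    return "'" + label.replace("'", "''") + "'"


# ---------------------------------------------------------------------------
# character matrices
# ---------------------------------------------------------------------------


def read_nexus_matrix(path: str | Path, dialect: str = "tolerant") -> CharacterMatrix:
    """Read a categorical character matrix from a NEXUS DATA/CHARACTERS block.

    ``dialect="strict"`` enforces the #NEXUS header, declared dimensions and
    declared state symbols; ``"tolerant"`` infers what it can.
    """
    if dialect not in ("strict", "tolerant"):
        raise ValueError(f"unknown dialect {dialect!r}")
    strict = dialect == "strict"
    text = Path(path).read_text()
    if strict and not text.lstrip().lower().startswith("#nexus"):
        raise ParseError("file does not start with #NEXUS", 1)
    blocks = _find_blocks(_strip_comments(text))
    block = next(
        ((n, b, l) for n, b, l in blocks if n in ("data", "characters")), None
    )
    if block is None:
        raise ParseError("no DATA or CHARACTERS block found", 1)
    _, body, start_line = block

    ntax = nchar = None
    missing_sym, gap_sym = "?", "-"
    symbols: str | None = None
    interleave = False
    matrix_cmd: tuple[str, int] | None = None
    charlabels: list[str] = []

    for cmd, line in _commands(body, start_line):
        head = cmd.split(None, 1)[0].lower()
        if head == "dimensions":
            kv = _parse_keyvals(cmd)
            if "ntax" in kv:
                ntax = int(kv["ntax"])
            if "nchar" in kv:
                nchar = int(kv["nchar"])
        elif head == "format":
            kv = _parse_keyvals(cmd)
            missing_sym = kv.get("missing", missing_sym)
            gap_sym = kv.get("gap", gap_sym)
            if "symbols" in kv:
                symbols = kv["symbols"].replace(" ", "")
            interleave = "interleave" in kv and kv.get("interleave", "") != "no"
        elif head == "charlabels":
            rest = cmd.split(None, 1)[1] if len(cmd.split(None, 1)) > 1 else ""
            charlabels = [
                _normalize_label(m.group(1) or m.group(2), bool(m.group(1)))
                for m in _LABEL_RE.finditer(rest)
            ]
        elif head == "matrix":
            matrix_cmd = (cmd, line)

    if matrix_cmd is None:
        raise ParseError("block has no MATRIX command", start_line)
    if nchar is None:
        raise ParseError("DIMENSIONS did not declare NCHAR", start_line)
    if strict and ntax is None:
        raise ParseError("DIMENSIONS did not declare NTAX", start_line)

    legal = set(symbols) if symbols else None
    rows = _parse_matrix_rows(
        matrix_cmd[0], matrix_cmd[1], nchar, missing_sym, gap_sym, legal,
        strict, interleave,
    )
    if ntax is not None and len(rows) != ntax:
        msg = f"declared NTAX={ntax} but matrix has {len(rows)} taxa"
        if strict:
            raise ParseError(msg, matrix_cmd[1])
    taxa = [t for t, _ in rows]
    if len(set(taxa)) != len(taxa):
        dupes = sorted({t for t in taxa if taxa.count(t) > 1})
        raise ValidationError(f"duplicate taxon label(s) in matrix: {dupes}")

    characters = _infer_characters(rows, nchar, charlabels)
    cells = [row for _, row in rows]
    return CharacterMatrix(taxa, characters, cells)


def _infer_characters(
    rows: list[tuple[str, list[CellValue]]],
    nchar: int,
    labels: Sequence[str],
) -> list[CharacterDefinition]:
    characters = []
    for j in range(nchar):
        observed = [s for _, row in rows for s in row[j].states]
        max_obs = max(observed, default=1)
        if max_obs > 2:
            taxon = next(t for t, row in rows if max(row[j].states, default=0) > 2)
            raise ValidationError(
                f"taxon {taxon!r}, character {j + 1}: state {max_obs} exceeds "
                "the ternary maximum supported by this pipeline"
            )
        label = labels[j] if j < len(labels) else ""
        characters.append(
            CharacterDefinition(index=j + 1, label=label, max_state=max(1, max_obs))
        )
    return characters


def _parse_matrix_rows(
    cmd: str,
    cmd_line: int,
    nchar: int,
    missing_sym: str,
    gap_sym: str,
    legal: set[str] | None,
    strict: bool,
    interleave: bool,
) -> list[tuple[str, list[CellValue]]]:
    body = cmd.split(None, 1)[1] if len(cmd.split(None, 1)) > 1 else ""
    order: list[str] = []
    data: dict[str, list[CellValue]] = {}

    def parse_states(chunk: str, taxon: str, line: int) -> list[CellValue]:
        cells: list[CellValue] = []
        i = 0
        while i < len(chunk):
            ch = chunk[i]
            if ch.isspace():
                i += 1
                continue
            if ch in "({":
                close = ")" if ch == "(" else "}"
                j = chunk.find(close, i)
                if j < 0:
                    raise ParseError(
                        f"taxon {taxon!r}: unclosed multistate bracket", line
                    )
                members = [
                    c for c in chunk[i + 1 : j] if not c.isspace() and c != ","
                ]
                states = []
                for c in members:
                    states.append(_symbol_state(c, taxon, len(data.get(taxon, [])) + len(cells) + 1, legal, strict, line))
                if len(set(states)) >= 2:
                    cells.append(CellValue.ambiguous(states))
                elif states:
                    cells.append(CellValue.defined(states[0]))
                else:
                    cells.append(CellValue.missing())
                i = j + 1
            elif ch == missing_sym or ch == gap_sym:
                cells.append(CellValue.missing())
                i += 1
            else:
                col = len(data.get(taxon, [])) + len(cells) + 1
                cells.append(CellValue.defined(_symbol_state(ch, taxon, col, legal, strict, line)))
                i += 1
        return cells

    lines = body.split("\n")
    line_no = cmd_line
    pending_taxon: str | None = None
    for raw in lines:
        stripped = raw.strip()
        if stripped:
            # continuation of a wrapped row: line starts with state characters
            if (
                not interleave
                and pending_taxon is not None
                and len(data[pending_taxon]) < nchar
                and _looks_like_states(stripped, missing_sym, gap_sym)
            ):
                data[pending_taxon].extend(
                    parse_states(stripped, pending_taxon, line_no)
                )
            else:
                m = _LABEL_RE.match(stripped)
                if m is None:
                    raise ParseError("cannot parse matrix row", line_no)
                taxon = _normalize_label(m.group(1) or m.group(2), bool(m.group(1)))
                rest = stripped[m.end() :]
                if taxon not in data:
                    data[taxon] = []
                    order.append(taxon)
                elif not interleave:
                    raise ValidationError(
                        f"duplicate taxon label(s) in matrix: [{taxon!r}]"
                    )
                data[taxon].extend(parse_states(rest, taxon, line_no))
                pending_taxon = taxon
        line_no += 1

    rows = []
    for taxon in order:
        cells = data[taxon]
        if len(cells) != nchar:
            raise ParseError(
                f"taxon {taxon!r}: {len(cells)} cells parsed, NCHAR={nchar}",
                cmd_line,
            )
        rows.append((taxon, cells))
    return rows


def _looks_like_states(s: str, missing_sym: str, gap_sym: str) -> bool:
    return all(
        c.isdigit() or c in f"(){{}}{missing_sym}{gap_sym}, " for c in s
    )


def _symbol_state(
    ch: str, taxon: str, column: int, legal: set[str] | None, strict: bool,
    line: int,
) -> int:
    if legal is not None and ch not in legal:
        raise ValidationError(
            f"taxon {taxon!r}, character {column}: state symbol {ch!r} is not "
            f"among the declared symbols"
        )
    if not ch.isdigit():
        raise ValidationError(
            f"taxon {taxon!r}, character {column}: unsupported state symbol {ch!r}"
        )
    return int(ch)


def write_nexus_matrix(matrix: CharacterMatrix, path: str | Path) -> None:
    """Write a matrix as a NEXUS DATA block that re-reads identically."""
    matrix.validate()
    max_state = max(c.max_state for c in matrix.characters)
    symbols = "".join(str(s) for s in range(max_state + 1))
    lines = [
        "#NEXUS",
        "",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};",
        f'    FORMAT DATATYPE=STANDARD MISSING=? GAP=- SYMBOLS="{symbols}";',
    ]
    if any(c.label for c in matrix.characters):
        labs = " ".join(
            _quote_label(c.label) if c.label else "_" for c in matrix.characters
        )
        lines.append(f"    CHARLABELS {labs};")
    lines.append("    MATRIX")
    width = max(len(_quote_label(t)) for t in matrix.taxa) + 2
    for taxon, row in zip(matrix.taxa, matrix.cells):
        cells = []
        for cell in row:
            if cell.is_missing:
                cells.append("?")
            elif cell.is_defined:
                cells.append(str(cell.state))
            else:
                cells.append("(" + "".join(str(s) for s in sorted(cell.states)) + ")")
        lines.append(f"    {_quote_label(taxon):<{width}}{''.join(cells)}")
    lines += ["    ;", "END;", ""]
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------


def write_distance_matrix(
    d: DistanceMatrix, path: str | Path, format: str = "phylip_square"
) -> None:
    """Write a distance matrix (``phylip_square`` or ``nexus_distances``)."""
    d.validate()
    if format == "phylip_square":
        lines = [f"{d.n_taxa}"]
        for i, taxon in enumerate(d.taxa):
            vals = " ".join(f"{v:.8g}" for v in d.values[i])
            lines.append(f"{_quote_label(taxon)}  {vals}")
    elif format == "nexus_distances":
        lines = [
            "#NEXUS",
            "",
            "BEGIN TAXA;",
            f"    DIMENSIONS NTAX={d.n_taxa};",
            "    TAXLABELS " + " ".join(_quote_label(t) for t in d.taxa) + ";",
            "END;",
            "",
            "BEGIN DISTANCES;",
            f"    DIMENSIONS NTAX={d.n_taxa};",
            "    FORMAT TRIANGLE=BOTH DIAGONAL LABELS;",
            "    MATRIX",
        ]
        for i, taxon in enumerate(d.taxa):
            vals = " ".join(f"{v:.8g}" for v in d.values[i])
            lines.append(f"        {_quote_label(taxon)}  {vals}")
        lines += ["    ;", "END;", ""]
    else:
        raise ValueError(f"unknown distance format {format!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_distance_matrix(path: str | Path, format: str = "phylip_square") -> DistanceMatrix:
    text = Path(path).read_text()
    if format == "phylip_square":
        rows = [ln for ln in text.splitlines() if ln.strip()]
        if not rows:
            raise ParseError("empty distance file", 1)
        try:
            n = int(rows[0].split()[0])
        except ValueError:
            raise ParseError("first line must give the taxon count", 1) from None
        taxa, values = [], []
        for k, ln in enumerate(rows[1 : n + 1], start=2):
            m = _LABEL_RE.match(ln.strip())
            if m is None:
                raise ParseError("cannot parse distance row", k)
            taxa.append(_normalize_label(m.group(1) or m.group(2), bool(m.group(1))))
            values.append([float(x) for x in ln.strip()[m.end() :].split()])
        mat = np.array(values, dtype=float)
        if mat.shape != (n, n):
            raise ParseError(f"expected {n}x{n} matrix, got {mat.shape}", 2)
        return DistanceMatrix(taxa, mat)
    if format == "nexus_distances":
        blocks = _find_blocks(_strip_comments(text))
        taxa: list[str] = []
        for name, body, start in blocks:
            if name == "taxa":
                for cmd, _ in _commands(body, start):
                    if cmd.split(None, 1)[0].lower() == "taxlabels":
                        rest = cmd.split(None, 1)[1]
                        taxa = [
                            _normalize_label(m.group(1) or m.group(2), bool(m.group(1)))
                            for m in _LABEL_RE.finditer(rest)
                        ]
        for name, body, start in blocks:
            if name == "distances":
                for cmd, line in _commands(body, start):
                    if cmd.split(None, 1)[0].lower() == "matrix":
                        rows = [
                            ln.strip()
                            for ln in cmd.split(None, 1)[1].splitlines()
                            if ln.strip()
                        ]
                        got_taxa, values = [], []
                        for ln in rows:
                            m = _LABEL_RE.match(ln)
                            got_taxa.append(
                                _normalize_label(m.group(1) or m.group(2), bool(m.group(1)))
                            )
                            values.append([float(x) for x in ln[m.end() :].split()])
                        return DistanceMatrix(got_taxa, np.array(values, dtype=float))
        raise ParseError("no DISTANCES block with MATRIX found", 1)
    raise ValueError(f"unknown distance format {format!r}")


# ---------------------------------------------------------------------------
# split systems
# ---------------------------------------------------------------------------


def write_splits_nexus(splits: SplitSystem, path: str | Path) -> None:
    """Write a TAXA + SPLITS NEXUS file loadable in a splits-graph viewer."""
    n = splits.n_taxa
    for s in splits.splits:
        if any(i < 0 or i >= n for i in s.side_a):
            raise ValidationError("split references a taxon outside the taxon set")
    order = splits.circular_order or CircularOrdering(tuple(range(n)))
    lines = [
        "#NEXUS",
        "",
        "BEGIN TAXA;",
        f"    DIMENSIONS NTAX={n};",
        "    TAXLABELS",
    ]
    lines += [f"        [{i + 1}] {_quote_label(t)}" for i, t in enumerate(splits.taxa)]
    lines += [
        "    ;",
        "END;",
        "",
        "BEGIN SPLITS;",
        f"    DIMENSIONS NTAX={n} NSPLITS={len(splits.splits)};",
        "    FORMAT LABELS=NO WEIGHTS=YES CONFIDENCES=NO INTERVALS=NO;",
        "    CYCLE " + " ".join(str(i + 1) for i in order.order) + ";",
        "    MATRIX",
    ]
    for k, s in enumerate(splits.splits, start=1):
        ids = " ".join(str(i + 1) for i in sorted(s.side_a))
        lines.append(f"        [{k}] {s.weight:.8g} {ids},")
    lines += ["    ;", "END;", ""]
    Path(path).write_text("\n".join(lines))


def read_splits_nexus(path: str | Path) -> SplitSystem:
    text = _strip_comments(Path(path).read_text())
    # the [k] row markers above are comments and were stripped already
    blocks = _find_blocks(text)
    taxa: list[str] = []
    for name, body, start in blocks:
        if name == "taxa":
            for cmd, _ in _commands(body, start):
                if cmd.split(None, 1)[0].lower() == "taxlabels":
                    rest = cmd.split(None, 1)[1]
                    taxa = [
                        _normalize_label(m.group(1) or m.group(2), bool(m.group(1)))
                        for m in _LABEL_RE.finditer(rest)
                    ]
    if not taxa:
        raise ParseError("no TAXA block found", 1)
    n = len(taxa)
    cycle: CircularOrdering | None = None
    splits: list[Split] = []
    for name, body, start in blocks:
        if name != "splits":
            continue
        for cmd, line in _commands(body, start):
            head = cmd.split(None, 1)[0].lower()
            if head == "cycle":
                ids = [int(x) - 1 for x in cmd.split()[1:]]
                cycle = CircularOrdering(tuple(ids))
            elif head == "matrix":
                for ln in cmd.split(None, 1)[1].splitlines():
                    ln = ln.strip().rstrip(",")
                    if not ln:
                        continue
                    parts = ln.split()
                    weight = float(parts[0])
                    ids = [int(x) - 1 for x in parts[1:]]
                    splits.append(Split.of(ids, n, weight))
    kind = "circular" if cycle is not None else "frequency"
    return SplitSystem(taxa=taxa, splits=splits, circular_order=cycle, kind=kind)


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------


def write_newick_tree(tree, path: str | Path) -> None:
    """Write an unrooted tree with branch lengths as Newick."""
    Path(path).write_text(tree.to_newick() + "\n")


def read_newick_tree(path: str | Path, taxa: Sequence[str] | None = None):
    """Read a Newick tree into the pipeline's tree structure (via dendropy)."""
    import dendropy

    from .tree_inference import PhyloTree

    dt = dendropy.Tree.get(path=str(Path(path)), schema="newick")
    dt.deroot()  # work with the unrooted shape

    adjacency: dict[int, dict[int, float]] = {}
    leaf_labels: dict[int, str] = {}
    ids: dict = {}

    def nid(node) -> int:
        if node not in ids:
            ids[node] = len(ids)
        return ids[node]

    for edge in dt.preorder_edge_iter():
        if edge.tail_node is None or edge.head_node is None:
            continue
        a, b = nid(edge.tail_node), nid(edge.head_node)
        length = float(edge.length) if edge.length is not None else 1.0
        adjacency.setdefault(a, {})[b] = length
        adjacency.setdefault(b, {})[a] = length
    for leaf in dt.leaf_node_iter():
        leaf_labels[nid(leaf)] = leaf.taxon.label
    tree = PhyloTree(
        taxa=list(taxa) if taxa is not None else sorted(leaf_labels.values()),
        adjacency=adjacency,
        leaf_labels=leaf_labels,
    )
    tree.validate()
    return tree
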