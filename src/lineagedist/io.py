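"""Reading and writing lineage data.

Three on-disk dialects are supported:

* the flat lineage-tracing dialect used by large C. elegans screens — one row
  per cell, the cell name followed by one value column per imaging timepoint
  the cell existed (cycle time = number of non-empty columns x 1.25 min at
  the standard imaging frequency);
* a native TSV dialect (``cell<TAB>cycle_time_min``) used for fixtures and
  synthetic data, chosen to round-trip bit-exactly;
* Newick, one tree per founder root, with branch lengths = cycle times.

Time-cutoff truncation (per-embryo curation boundaries shipped alongside such
datasets) and homeotic-transformation annotation tables are handled here too.
"""

from __future__ import annotations

import io as _io
import warnings
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

from .core import (
    IntegrityError,
    Lineage,
    NamingError,
    Sublineage,
    birth_time,
    child_names,
    children_of,
    is_normalized_name,
    parse_cell_name,
    validate_lineage,
)


class FormatError(ValueError):
    """Malformed input file."""


_NA_TOKENS = {"", "na", "nan", "none", "null"}


def read_du_lineage(path, minutes_per_timepoint: float = 1.25, embryo_id: str | None = None) -> Lineage:
    """Read a flat screen-dialect lineage file.

    Each row holds a cell name followed by per-timepoint value columns; only
    the *count* of non-empty columns is used: cycle time = count x
    ``minutes_per_timepoint`` (default 1.25 min, the standard imaging
    interval).  Structural violations are reported as warnings, not errors,
    because partially curated embryos are expected in screen data.
    """
    path = Path(path)
    cells: dict[str, float] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            tokens = line.rstrip("\n").split("\t")
            if len(tokens) == 1:
                tokens = line.split()
            name = tokens[0].strip()
            try:
                parse_cell_name(name)
            except NamingError as e:
                raise FormatError(f"{path}, row {i}: {e}") from e
            if name in cells:
                raise FormatError(f"{path}, row {i}: duplicate cell name {name!r}")
            n_timepoints = sum(1 for t in tokens[1:] if t.strip().lower() not in _NA_TOKENS)
            if n_timepoints < 1:
                raise FormatError(f"{path}, row {i}: cell {name!r} has no timepoint columns")
            cells[name] = n_timepoints * minutes_per_timepoint
    if not cells:
        raise FormatError(f"{path}: empty lineage file")
    lin = Lineage(embryo_id=embryo_id or path.stem, cells=cells, meta={"source": str(path)})
    for v in validate_lineage(lin):
        warnings.warn(f"{path}: {v}", stacklevel=2)
    return lin


def write_tsv(obj: Lineage | Sublineage, path) -> None:
    """Write the native TSV dialect: header ``cell<TAB>cycle_time_min``, UTF-8."""
    cells = obj.cells
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cell\tcycle_time_min\n")
        for name in sorted(cells):
            fh.write(f"{name}\t{cells[name]!r}\n")


def read_tsv(path, embryo_id: str | None = None) -> Lineage:
    """Read the native TSV dialect back into a Lineage."""
    path = Path(path)
    cells: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("cell"):
            raise FormatError(f"{path}: missing native-TSV header")
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            try:
                name, value = line.rstrip("\n").split("\t")
            except ValueError as e:
                raise FormatError(f"{path}, row {i}: expected 2 columns") from e
            if name in cells:
                raise FormatError(f"{path}, row {i}: duplicate cell name {name!r}")
            cells[name.strip()] = float(value)
    if not cells:
        raise FormatError(f"{path}: empty lineage file")
    return Lineage(embryo_id=embryo_id or path.stem, cells=cells, meta={"source": str(path)})


def apply_time_cutoff(lineage: Lineage, cutoff: float, censored_policy: str = "drop") -> Lineage:
    """Truncate a lineage at *cutoff* minutes from the first recorded timepoint.

    Cells born at or after the cutoff are removed.  Cells whose cycle spans
    the cutoff are censored: ``drop`` (default) removes them, ``keep`` retains
    them with the observed duration clipped to ``cutoff - birth``.  Truncation
    can orphan a lone sibling (the other daughter spanned the cutoff); such
    single children are pruned, with their subtrees, until the binary
    invariant holds again.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    if censored_policy not in ("drop", "keep"):
        raise ValueError(f"censored_policy must be 'drop' or 'keep', got {censored_policy!r}")
    kept: dict[str, float] = {}
    for name, t in lineage.cells.items():
        b = birth_time(lineage, name)
        if b >= cutoff:
            continue
        if b + t > cutoff:
            if censored_policy == "drop":
                continue
            kept[name] = cutoff - b
        else:
            kept[name] = t
    # prune lone daughters introduced by censoring until the tree is binary again
    changed = True
    while changed:
        changed = False
        for name in list(kept):
            present = {c for c in child_names(name) if c in kept}
            if len(present) == 1:
                lone = present.pop()
                stack = [lone]
                while stack:
                    cur = stack.pop()
                    kept.pop(cur, None)
                    stack.extend(c for c in child_names(cur) if c in kept)
                changed = True
    meta = dict(lineage.meta)
    meta["cutoff_min"] = cutoff
    meta["censored_policy"] = censored_policy
    return Lineage(embryo_id=lineage.embryo_id, cells=kept, meta=meta)


def _fmt_len(x: float) -> str:
    # integers print bare; otherwise the shortest exact round-trip form
    return str(int(x)) if x == int(x) else repr(float(x))


def export_newick(obj: Lineage | Sublineage, root: str | None = None) -> str:
    """Serialize a single rooted tree as Newick with cycle times as branch lengths.

    Forests must be exported one founder root at a time (pass *root*).
    """
    cells = obj.cells
    if root is None:
        if isinstance(obj, Lineage):
            roots = obj.roots()
        else:
            from .core import parent_of

            roots = sorted(n for n in cells if parent_of(n) not in cells)
        if len(roots) != 1:
            raise ValueError(
                f"input is a forest with roots {roots}; export each root separately"
            )
        root = roots[0]
    if root not in cells:
        raise KeyError(root)

    def build(name: str) -> str:
        kids = sorted(children_of(obj, name))
        label = f"{name}:{_fmt_len(cells[name])}"
        if not kids:
            return label
        # anterior-first child order for reproducible output
        kids.sort(key=lambda k: (0 if k[-1] in "ald" or k in ("AB", "EMS", "MS", "C", "D", "Z2") else 1, k))
        return "(" + ",".join(build(k) for k in kids) + ")" + label

    return build(root) + ";"


def read_newick(text: str) -> dict[str, float]:
    """Parse a Newick string back into a name → branch-length mapping."""
    import dendropy

    tree = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=False)
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        label = node.taxon.label if node.taxon is not None else node.label
        if label is None:
            continue
        label = label.replace(" ", "_")
        out[label] = float(node.edge.length) if node.edge.length is not None else 0.0
    return out


class TransformationAnnotation(NamedTuple):
    gene: str
    embryo_id: str
    origin_root: str
    destination_root: str


_DEFAULT_COLMAP = {
    "gene": ("gene", "Gene", "gene_name"),
    "embryo_id": ("embryo", "embryo_id", "Embryo", "lineage_file"),
    "origin_root": ("origin", "origin_root", "Origin", "origin_lineage"),
    "destination_root": ("destination", "destination_root", "Destination", "destination_lineage"),
}


def read_annotation_table(path, colmap: dict[str, str] | None = None) -> list[TransformationAnnotation]:
    """Read a homeotic-transformation annotation table (CSV/TSV).

    The column layout of deposited annotation spreadsheets varies, so the
    mapping from our field names to column headers is configurable; by
    default common header variants are recognized.  Origin/destination cell
    names are validated against the naming rules.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    resolved: dict[str, str] = {}
    for fieldname, candidates in _DEFAULT_COLMAP.items():
        if colmap and fieldname in colmap:
            candidates = (colmap[fieldname],)
        col = next((c for c in candidates if c in df.columns), None)
        if col is None:
            raise FormatError(f"annotation table missing a column for {fieldname!r}")
        resolved[fieldname] = col
    records: list[TransformationAnnotation] = []
    for _, row in df.iterrows():
        origin = str(row[resolved["origin_root"]]).strip()
        dest = str(row[resolved["destination_root"]]).strip()
        parse_cell_name(origin)  # NamingError on unknown roots
        parse_cell_name(dest)
        records.append(
            TransformationAnnotation(
                gene=str(row[resolved["gene"]]).strip(),
                embryo_id=str(row[resolved["embryo_id"]]).strip(),
                origin_root=origin,
                destination_root=dest,
            )
        )
    return records


def read_cutoff_table(path) -> dict[str, float]:
    """Read per-embryo time cutoffs: a delimited table with embryo and minutes columns."""
    df = pd.read_csv(path, sep=None, engine="python")
    embryo_col = next((c for c in ("embryo", "embryo_id", "Embryo") if c in df.columns), df.columns[0])
    cutoff_col = next(
        (c for c in ("cutoff_min", "cutoff", "minutes", "time_cutoff") if c in df.columns),
        df.columns[1],
    )
    out: dict[str, float] = {}
    for _, row in df.iterrows():
        cutoff = float(row[cutoff_col])
        if cutoff <= 0:
            raise FormatError(f"cutoff for {row[embryo_col]!r} must be > 0")
        out[str(row[embryo_col]).strip()] = cutoff
    return out


def apply_cutoffs(cohort: Iterable[Lineage], cutoffs: dict[str, float], censored_policy: str = "drop") -> list[Lineage]:
    """Apply a cutoff table to a cohort; unmatched embryos pass through with a warning."""
    out = []
    for lin in cohort:
        if lin.embryo_id in cutoffs:
            out.append(apply_time_cutoff(lin, cutoffs[lin.embryo_id], censored_policy))
        else:
            warnings.warn(f"no cutoff annotation for embryo {lin.embryo_id!r}; left untruncated", stacklevel=2)
            out.append(lin)
    return out
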