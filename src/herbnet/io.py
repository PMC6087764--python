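"""Readers and writers for the tabular inputs and outputs.

All tables are UTF-8, tab-separated, with a header row. Numeric fields may
use the typographic minus sign (U+2212) as printed in the source tables; it
is normalised to ASCII ``-`` on input and preserved as ASCII on output.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .types import Component, Fingerprint, GIClass, TargetProtein

__all__ = [
    "SchemaError",
    "RowParseError",
    "read_component_table",
    "write_component_table",
    "read_target_table",
    "write_target_table",
    "read_edge_list",
    "write_edge_list",
    "read_annotation_map",
    "write_annotation_map",
    "read_fingerprints",
    "write_fingerprints",
    "load_zzw_components",
    "load_zzw_targets",
    "zzw_fixture_path",
]


class SchemaError(ValueError):
    """A required column is missing or the table layout is invalid."""


class RowParseError(ValueError):
    """A row holds an unparseable value; carries the offending row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


_MINUS = "−"

# Accepted header aliases (lower-cased) -> canonical field name
_COMPONENT_ALIASES = {
    "id": "id",
    "molecule_name": "name",
    "name": "name",
    "herb": "herb",
    "mw": "mw",
    "ob": "ob",
    "caco-2": "caco2",
    "caco2": "caco2",
    "dl": "dl",
    "mlogp": "mlogp",
    "nhacc": "nhacc",
    "nhdon": "nhdon",
    "tpsa": "tpsa",
    "gi absorption": "gi",
    "gi": "gi",
}

_REQUIRED_COMPONENT_COLS = (
    "id", "name", "mw", "ob", "caco2", "dl", "mlogp", "nhacc", "nhdon", "tpsa", "gi",
)

_HERB_PREFIXES = {"ZS": "ZHISHI", "BZ": "BAIZHU"}


def _to_float(value: object, row: int, col: str) -> float:
    text = str(value).strip().replace(_MINUS, "-")
    try:
        return float(text)
    except ValueError:
        raise RowParseError(row, f"cannot parse {col}={value!r} as a number") from None


def _to_int(value: object, row: int, col: str) -> int:
    text = str(value).strip().replace(_MINUS, "-")
    try:
        return int(text)
    except ValueError:
        raise RowParseError(row, f"cannot parse {col}={value!r} as an integer") from None


def infer_herb(component_id: str) -> str | None:
    """Infer the herb label from a ZS/BZ-style id prefix, else None."""
    for prefix, herb in _HERB_PREFIXES.items():
        if component_id.upper().startswith(prefix):
            return herb
    return None


def read_component_table(path: str | Path) -> list[Component]:
    """Read a component property table.

    The herb is taken from an explicit ``herb`` column when present,
    otherwise inferred from the ZS/BZ id prefix. GI classes are parsed
    case-insensitively; any value other than high/low raises.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols: dict[str, str] = {}
    for col in df.columns:
        canon = _COMPONENT_ALIASES.get(col.strip().strip("*").lower())
        if canon is not None and canon not in cols:
            cols[canon] = col
    missing = [c for c in _REQUIRED_COMPONENT_COLS if c not in cols]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    components: list[Component] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        cid = str(rec[cols["id"]]).strip()
        if cid in seen:
            raise ValueError(f"duplicate component id {cid!r}")
        seen.add(cid)
        if "herb" in cols and str(rec[cols["herb"]]).strip():
            herb = str(rec[cols["herb"]]).strip().upper()
        else:
            herb = infer_herb(cid)
            if herb is None:
                raise RowParseError(i, f"cannot infer herb for id {cid!r} (no herb column)")
        try:
            gi = GIClass.parse(rec[cols["gi"]])
        except ValueError as exc:
            raise RowParseError(i, str(exc)) from None
        components.append(
            Component(
                id=cid,
                herb=herb,
                name=str(rec[cols["name"]]).strip(),
                mw=_to_float(rec[cols["mw"]], i, "mw"),
                ob=_to_float(rec[cols["ob"]], i, "ob"),
                caco2=_to_float(rec[cols["caco2"]], i, "caco2"),
                dl=_to_float(rec[cols["dl"]], i, "dl"),
                mlogp=_to_float(rec[cols["mlogp"]], i, "mlogp"),
                nhacc=_to_int(rec[cols["nhacc"]], i, "nhacc"),
                nhdon=_to_int(rec[cols["nhdon"]], i, "nhdon"),
                tpsa=_to_float(rec[cols["tpsa"]], i, "tpsa"),
                gi=gi,
            )
        )
    return components


def _fmt(x: float) -> str:
    # repr gives the shortest round-tripping decimal for a float
    return repr(float(x))


def write_component_table(components: Sequence[Component], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as f:
        f.write("id\therb\tname\tmw\tob\tcaco2\tdl\tmlogp\tnhacc\tnhdon\ttpsa\tgi\n")
        for c in components:
            f.write(
                "\t".join(
                    [
                        c.id, c.herb, c.name,
                        _fmt(c.mw), _fmt(c.ob), _fmt(c.caco2), _fmt(c.dl),
                        _fmt(c.mlogp), str(c.nhacc), str(c.nhdon), _fmt(c.tpsa),
                        c.gi.value,
                    ]
                )
                + "\n"
            )


def read_target_table(path: str | Path) -> list[TargetProtein]:
    """Read a target table with Gene / Protein name / Uniprot ID columns."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    aliases = {"gene": "gene", "protein name": "protein_name",
               "protein_name": "protein_name", "uniprot id": "uniprot",
               "uniprot": "uniprot", "uniprot_id": "uniprot"}
    cols: dict[str, str] = {}
    for col in df.columns:
        canon = aliases.get(col.strip().strip("*").lower())
        if canon is not None and canon not in cols:
            cols[canon] = col
    missing = [c for c in ("gene", "protein_name", "uniprot") if c not in cols]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    targets: list[TargetProtein] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        gene = str(rec[cols["gene"]]).strip()
        if gene in seen:
            raise ValueError(f"duplicate gene symbol {gene!r}")
        seen.add(gene)
        targets.append(
            TargetProtein(
                gene=gene,
                protein_name=str(rec[cols["protein_name"]]).strip(),
                uniprot=str(rec[cols["uniprot"]]).strip(),
            )
        )
    return targets


def write_target_table(targets: Sequence[TargetProtein], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as f:
        f.write("gene\tprotein_name\tuniprot\n")
        for t in targets:
            f.write(f"{t.gene}\t{t.protein_name}\t{t.uniprot}\n")


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column TSV edge list (optional header).

    Duplicate pairs are deduplicated (first occurrence kept) with a warning
    reporting the count; self-loops are a bipartite violation and raise.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    with open(path, encoding="utf-8") as f:
        for i, line in enumerate(f):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise RowParseError(i, f"expected two tab-separated columns, got {line!r}")
            a, b = parts[0].strip(), parts[1].strip()
            if i == 0 and (a.lower() in ("source", "component", "left")
                           or b.lower() in ("target", "right")):
                continue  # header row
            if a == b:
                raise ValueError(f"self-loop {a!r} -> {b!r} violates bipartiteness")
            if (a, b) in seen:
                n_dup += 1
                continue
            seen.add((a, b))
            pairs.append((a, b))
    if n_dup:
        warnings.warn(f"deduplicated {n_dup} repeated edge(s)", stacklevel=2)
    return pairs


def write_edge_list(pairs: Iterable[tuple[str, str]], path: str | Path,
                    header: tuple[str, str] = ("source", "target")) -> None:
    with open(path, "w", encoding="utf-8") as f:
        f.write(f"{header[0]}\t{header[1]}\n")
        for a, b in pairs:
            f.write(f"{a}\t{b}\n")


def read_annotation_map(path: str | Path) -> dict[str, set[str]]:
    """Read an ``annotation_id<TAB>gene`` table into annotation -> gene set."""
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as f:
        for i, line in enumerate(f):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise RowParseError(i, f"expected two tab-separated columns, got {line!r}")
            ann, gene = parts[0].strip(), parts[1].strip()
            if i == 0 and ann.lower() in ("annotation", "annotation_id", "disease", "pathway"):
                continue
            out.setdefault(ann, set()).add(gene)
    return out


def write_annotation_map(annotations: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as f:
        f.write("annotation_id\tgene\n")
        for ann in sorted(annotations):
            for gene in sorted(annotations[ann]):
                f.write(f"{ann}\t{gene}\n")


def read_fingerprints(path: str | Path) -> list[Fingerprint]:
    """Read ``component_id<TAB>bitstring`` fingerprints (equal lengths)."""
    fps: list[Fingerprint] = []
    length: int | None = None
    with open(path, encoding="utf-8") as f:
        for i, line in enumerate(f):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise RowParseError(i, f"expected two tab-separated columns, got {line!r}")
            cid, bitstr = parts[0].strip(), parts[1].strip()
            if i == 0 and cid.lower() in ("component_id", "id"):
                continue
            if not set(bitstr) <= {"0", "1"}:
                raise RowParseError(i, f"fingerprint for {cid!r} is not a 0/1 string")
            if length is None:
                length = len(bitstr)
            elif len(bitstr) != length:
                raise RowParseError(i, f"fingerprint length {len(bitstr)} != {length}")
            fps.append(Fingerprint(component_id=cid, bits=tuple(int(b) for b in bitstr)))
    return fps


def write_fingerprints(fps: Sequence[Fingerprint], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as f:
        f.write("component_id\tbits\n")
        for fp in fps:
            f.write(f"{fp.component_id}\t{''.join(map(str, fp.bits))}\n")


# ---------------------------------------------------------------------------
# Packaged fixtures: the printed two-herb component and target tables.


def zzw_fixture_path(name: str) -> Path:
    """Path to a packaged fixture (``zzw_components.tsv`` / ``zzw_targets.tsv``)."""
    return Path(str(resources.files("herbnet.data").joinpath(name)))


def load_zzw_components() -> list[Component]:
    """The packaged 62-row component property table (45 Zhishi + 17 Baizhu)."""
    return read_component_table(zzw_fixture_path("zzw_components.tsv"))


def load_zzw_targets() -> list[TargetProtein]:
    """The packaged 133-row target protein table."""
    return read_target_table(zzw_fixture_path("zzw_targets.tsv"))
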