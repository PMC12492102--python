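"""Readers and writers for the pipeline's plain-text table dialects.

Five dialects, all TSV with a header row (writers prepend ``#`` provenance
comment lines, readers skip them):

* gene counts  — "Orthogroup" column + one column per species, an optional
  trailing "Total" column is ignored (the OrthoFinder GeneCount dialect);
* branch rates — og_id, branch_id, omega [, subst_rate];
* events       — og_id, branch_id, delta [, p_event, rapid];
* EC annotations — species, ec (one pair per line);
* pathways     — pathway_id, superpathway_id, name, has_reference,
  semicolon-joined EC list.

Clade definitions travel as YAML: a list of {name, type, leaves,
include_stem} mappings.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .tree import CladeSpec

__all__ = [
    "read_gene_counts", "write_gene_counts",
    "read_branch_rates", "write_branch_rates",
    "read_events", "write_events",
    "read_ec_annotations", "write_ec_annotations",
    "read_pathways", "write_pathways",
    "read_clades", "write_clades",
    "write_table",
]


def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def write_table(df: pd.DataFrame, path, provenance: str | None = None, index=True):
    """Write a TSV with optional leading ``#`` provenance comment."""
    path = Path(path)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_gene_counts(path) -> pd.DataFrame:
    df = _read_tsv(path)
    df = df.set_index(df.columns[0])
    df.index.name = "Orthogroup"
    drop = [c for c in df.columns if c.lower() == "total"]
    if drop:
        df = df.drop(columns=drop)
    df = df.astype(int)
    if (df.values < 0).any():
        raise ValueError("negative gene counts")
    return df


def write_gene_counts(df: pd.DataFrame, path, total: bool = True,
                      provenance: str | None = None):
    out = df.copy()
    if total:
        out["Total"] = df.sum(axis=1)
    write_table(out, path, provenance)


def read_branch_rates(path) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"og_id": str, "branch_id": str})
    need = {"og_id", "branch_id", "omega"}
    if not need <= set(df.columns):
        raise ValueError(f"rates table needs columns {sorted(need)}")
    if (df["omega"] <= 0).any():
        raise ValueError("omega must be strictly positive")
    return df


def write_branch_rates(df: pd.DataFrame, path, provenance: str | None = None):
    write_table(df, path, provenance, index=False)


def read_events(path) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"og_id": str, "branch_id": str})
    need = {"og_id", "branch_id", "delta"}
    if not need <= set(df.columns):
        raise ValueError(f"events table needs columns {sorted(need)}")
    return df


def write_events(df: pd.DataFrame, path, provenance: str | None = None):
    write_table(df, path, provenance, index=False)


def read_ec_annotations(path) -> dict[str, set[str]]:
    df = _read_tsv(path, dtype=str)
    if not {"species", "ec"} <= set(df.columns):
        raise ValueError("EC table needs columns species, ec")
    out: dict[str, set[str]] = {}
    for sp, ec in zip(df["species"], df["ec"]):
        out.setdefault(sp, set()).add(ec)
    return out


def write_ec_annotations(profiles: dict[str, set[str]], path,
                         provenance: str | None = None):
    rows = [(sp, ec) for sp in sorted(profiles) for ec in sorted(profiles[sp])]
    write_table(pd.DataFrame(rows, columns=["species", "ec"]), path, provenance, index=False)


def read_pathways(path) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"pathway_id": str, "superpathway_id": str, "name": str})
    need = {"pathway_id", "superpathway_id", "name", "has_reference", "ecs"}
    if not need <= set(df.columns):
        raise ValueError(f"pathway table needs columns {sorted(need)}")
    df["has_reference"] = df["has_reference"].astype(bool)
    df["ecs"] = [sorted(str(v).split(";")) for v in df["ecs"]]
    return df


def write_pathways(df: pd.DataFrame, path, provenance: str | None = None):
    out = df.copy()
    out["ecs"] = [";".join(sorted(e)) for e in out["ecs"]]
    write_table(out, path, provenance, index=False)


def read_clades(path) -> dict[str, CladeSpec]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    specs = {}
    for entry in data["clades"]:
        specs[entry["name"]] = CladeSpec(
            name=entry["name"],
            kind=entry.get("type", "mrca"),
            leaves=tuple(entry["leaves"]),
            include_stem=bool(entry.get("include_stem", False)),
        )
    return specs


def write_clades(specs: dict[str, CladeSpec], path):
    data = {
        "clades": [
            {
                "name": s.name,
                "type": s.kind,
                "leaves": sorted(s.leaves),
                "include_stem": s.include_stem,
            }
            for _, s in sorted(specs.items())
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
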