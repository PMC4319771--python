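"""Readers and writers for the pipeline's plain-text formats.

Pedigree and phenotypes travel as CSV; genotypes as PLINK PED/MAP text or
a one-line-per-animal dialect (ID, whitespace, contiguous 0/1/2/5 string,
5 = missing) common in animal-breeding software.  Write-then-read
round-trips reproduce the in-memory objects exactly, including missing
sentinels.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import (MISSING, MarkerPanel, PedigreeTable, TrueGeneticModel,
                      UNKNOWN_PARENT)

__all__ = [
    "write_pedigree", "read_pedigree",
    "write_phenotypes", "read_phenotypes",
    "write_plink", "read_plink",
    "write_genotype_lines", "read_genotype_lines",
    "write_truth", "read_truth",
]


def write_pedigree(ped: PedigreeTable, path) -> None:
    ped.records.to_csv(path, index=False)


def read_pedigree(path) -> PedigreeTable:
    df = pd.read_csv(path, dtype=str)
    if "sex" not in df.columns:
        df["sex"] = "F"
    if "generation" not in df.columns:
        df["generation"] = 0
    df["generation"] = df["generation"].astype(int)
    for col in ("sire", "dam"):
        df[col] = df[col].fillna(UNKNOWN_PARENT)
    return PedigreeTable(df.reset_index(drop=True))


def write_phenotypes(phen: pd.DataFrame, path) -> None:
    phen.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"animal": str, "sire": str,
                                  "herd_year": str, "year_season": str})
    df["y"] = df["y"].astype(np.int8)
    if df["animal"].duplicated().any():
        raise ValueError("duplicate animal IDs in phenotype file")
    return df


# ---------------------------------------------------------------- PLINK text

def write_plink(panel: MarkerPanel, prefix) -> tuple[Path, Path]:
    """Write chip-style .ped/.map text; alleles coded 1/2, missing 0 0."""
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    mm = panel.marker_map
    with open(map_path, "w") as fh:
        for _, row in mm.iterrows():
            fh.write(f"{row['chrom']}\t{row['marker']}\t0\t{row['bp']}\n")
    # genotype 0 -> "1 1", 1 -> "1 2", 2 -> "2 2", missing -> "0 0"
    allele_map = {0: "1 1", 1: "1 2", 2: "2 2", int(MISSING): "0 0"}
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(panel.ids):
            geno = " ".join(allele_map[int(g)] for g in panel.genotypes[i])
            fh.write(f"FAM {iid} 0 0 0 -9 {geno}\n")
    return ped_path, map_path


def read_plink(prefix) -> MarkerPanel:
    prefix = Path(prefix)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    mm = pd.read_csv(map_path, sep="\t", header=None,
                     names=["chrom", "marker", "cm", "bp"])
    marker_map = mm[["marker", "chrom", "bp"]].copy()
    m = len(marker_map)
    ids, rows = [], []
    code = {("1", "1"): 0, ("1", "2"): 1, ("2", "1"): 1, ("2", "2"): 2,
            ("0", "0"): int(MISSING)}
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} fields, "
                    f"got {len(parts)}")
            iid = parts[1]
            if iid in ids:
                raise ValueError(f"{ped_path}:{ln}: duplicate individual "
                                 f"ID {iid!r}")
            alleles = parts[6:]
            try:
                row = [code[(alleles[2 * j], alleles[2 * j + 1])]
                       for j in range(m)]
            except KeyError as exc:
                raise ValueError(
                    f"{ped_path}:{ln}: unrecognized allele pair {exc}"
                ) from exc
            ids.append(iid)
            rows.append(row)
    return MarkerPanel(ids=np.array(ids), genotypes=np.array(rows, dtype=np.int8),
                       marker_map=marker_map, allele_freqs=None)


# ------------------------------------------------- one-line genotype dialect

def write_genotype_lines(panel: MarkerPanel, path) -> None:
    """ID, space, contiguous 0/1/2 string with 5 for missing."""
    with open(path, "w") as fh:
        for i, iid in enumerate(panel.ids):
            s = "".join("5" if g == MISSING else str(int(g))
                        for g in panel.genotypes[i])
            fh.write(f"{iid} {s}\n")


def read_genotype_lines(path, marker_map: pd.DataFrame) -> MarkerPanel:
    ids, rows = [], []
    m = len(marker_map)
    decode = {"0": 0, "1": 1, "2": 2, "5": int(MISSING)}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 'ID genotypes'")
            iid, s = parts
            if iid in ids:
                raise ValueError(f"{path}:{ln}: duplicate individual ID {iid!r}")
            if len(s) != m:
                raise ValueError(f"{path}:{ln}: expected {m} genotype "
                                 f"characters, got {len(s)}")
            try:
                rows.append([decode[c] for c in s])
            except KeyError as exc:
                raise ValueError(f"{path}:{ln}: bad genotype code {exc}") from exc
            ids.append(iid)
    return MarkerPanel(ids=np.array(ids), genotypes=np.array(rows, dtype=np.int8),
                       marker_map=marker_map.reset_index(drop=True),
                       allele_freqs=None)


# -------------------------------------------------------------------- truth

def write_truth(truth: TrueGeneticModel, variances: dict, path) -> None:
    payload = {
        "qtl_indices": [int(i) for i in truth.qtl_indices],
        "qtl_effects": [float(e) for e in truth.qtl_effects],
        "liability_threshold": float(truth.liability_threshold),
        "variances": variances,
        "true_breeding_values": {
            str(k): float(v) for k, v in truth.true_breeding_values.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
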