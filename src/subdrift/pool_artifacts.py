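"""Sequencing-error and jumping-PCR rate estimation from pooled captures.

When individually indexed libraries are pooled for hybridization capture and
then PCR-amplified together, a nascent strand can switch templates between
libraries ("jumping PCR").  On fully inbred lines this produces a telltale
signature: at a site where pool-mates carry different homozygous alleles, a
library shows a low-frequency minor variant that is exactly the major allele
of another library in the *same* pool, at a rate well above the sequencing
error background.

The estimator buckets every read at a high-coverage locus into three
classes per (locus, focal substrain) cell:

* focal  — the substrain's own homozygous allele;
* jump   — a base that is the major allele of some other same-pool
  substrain and differs from the focal allele;
* error  — any remaining base.

``jump_freq`` is only meaningful where some in-pool substrain actually
differs at the locus; cells without such an informative difference are
excluded from the jump summaries (their ``error_freq`` still counts).
A base that could be either a jump or an error is assigned to the jump
bucket; ``jump_corrected = jump_freq - error_freq / 3`` is reported as an
optional deconvolved estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable

__all__ = ["PileupCounts", "ArtifactRates", "select_high_coverage", "estimate_artifact_rates"]

BASES = ("A", "C", "G", "T")
COUNT_COLUMNS = ["count_A", "count_C", "count_G", "count_T"]


@dataclass
class PileupCounts:
    """Per-locus per-substrain read base counts.

    ``records`` columns: chrom, pos, substrain, count_A, count_C, count_G,
    count_T.  ``pools`` maps pool name -> list of member substrains; pools
    must be disjoint and cover every substrain present.
    """

    records: pd.DataFrame
    pools: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        need = ["chrom", "pos", "substrain"] + COUNT_COLUMNS
        missing = [c for c in need if c not in self.records.columns]
        if missing:
            raise ValueError(f"pileup records missing columns: {missing}")
        if (self.records[COUNT_COLUMNS].to_numpy() < 0).any():
            raise ValueError("negative base counts")
        dup = self.records.duplicated(subset=["chrom", "pos", "substrain"])
        if dup.any():
            raise ValueError("duplicate (locus, substrain) pileup records")
        if self.pools:
            members = [s for ms in self.pools.values() for s in ms]
            if len(members) != len(set(members)):
                raise ValueError("pools are not disjoint")
            present = set(self.records["substrain"])
            if not present <= set(members):
                raise ValueError("pools do not cover all substrains in the pileup")

    @property
    def substrains(self) -> list[str]:
        return sorted(self.records["substrain"].unique())

    def loci(self) -> list[tuple[str, int]]:
        seen = self.records[["chrom", "pos"]].drop_duplicates()
        return list(map(tuple, seen.itertuples(index=False)))

    def pool_of(self, substrain: str) -> str:
        for name, members in self.pools.items():
            if substrain in members:
                return name
        raise KeyError(f"substrain {substrain!r} not in any pool")

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, pools: dict[str, list[str]] | None = None) -> "PileupCounts":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(df, pools or {})


@dataclass
class ArtifactRates:
    """Per-cell and summary artifact-rate estimates.

    ``cells`` columns: chrom, pos, substrain, depth, focal_freq, jump_freq,
    error_freq, jump_informative (bool: some in-pool substrain differs).
    Summaries are taken over jump-informative cells for the jump rate and
    over all cells for the error rate.
    """

    cells: pd.DataFrame
    n_loci_used: int

    def summary(self) -> dict:
        inf = self.cells[self.cells["jump_informative"]]
        out = {"n_loci_used": self.n_loci_used, "n_cells": len(self.cells)}
        for key, series in (
            ("error", self.cells["error_freq"]),
            ("jump", inf["jump_freq"]),
            ("jump_corrected", inf["jump_freq"] - inf["error_freq"] / 3.0),
        ):
            if len(series):
                out[f"{key}_min"] = float(series.min())
                out[f"{key}_max"] = float(series.max())
                out[f"{key}_mean"] = float(series.mean())
            else:
                out[f"{key}_min"] = out[f"{key}_max"] = out[f"{key}_mean"] = float("nan")
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {"summary": self.summary(), "cells": self.cells.to_dict(orient="records")}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    def report_text(self) -> str:
        """Human-readable summary, rates as percentages."""
        s = self.summary()

        def pct(x: float) -> str:
            return f"{100.0 * x:.2g}%"

        lines = [
            f"loci used: {s['n_loci_used']} ({s['n_cells']} substrain-locus cells)",
            f"sequencing error rate: {pct(s['error_min'])}-{pct(s['error_max'])} "
            f"(mean {pct(s['error_mean'])})",
            f"jumping-PCR rate:      {pct(s['jump_min'])}-{pct(s['jump_max'])} "
            f"(mean {pct(s['jump_mean'])})",
            f"jump rate, error-corrected mean: {pct(s['jump_corrected_mean'])}",
        ]
        return "\n".join(lines)


def select_high_coverage(pileup: PileupCounts, min_depth: int = 100) -> list[tuple[str, int]]:
    """Loci at which *every* substrain has total depth >= ``min_depth``."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    df = pileup.records.copy()
    df["depth"] = df[COUNT_COLUMNS].sum(axis=1)
    n_strains = len(pileup.substrains)
    keep = []
    for (chrom, pos), grp in df.groupby(["chrom", "pos"], sort=False):
        if len(grp) == n_strains and (grp["depth"] >= min_depth).all():
            keep.append((chrom, int(pos)))
    return keep


def estimate_artifact_rates(
    pileup: PileupCounts,
    loci: list[tuple[str, int]],
    truth: GenotypeTable,
) -> ArtifactRates:
    """Estimate per-cell error and jumping-PCR frequencies.

    ``truth`` supplies each substrain's homozygous (major) allele per locus;
    loci must be SNPs.  See the module docstring for the bucket rules.
    """
    if not pileup.pools:
        raise ValueError("pileup has no pool design; jump buckets undefined")
    key = {}
    for i in range(len(truth)):
        row = truth.variants.iloc[i]
        key[(row["chrom"], int(row["pos"]))] = i

    base_idx = {b: k for k, b in enumerate(BASES)}
    rows = []
    rec = pileup.records.set_index(["chrom", "pos", "substrain"])
    for chrom, pos in loci:
        if (chrom, pos) not in key:
            raise KeyError(f"locus {chrom}:{pos} absent from the genotype table")
        vi = key[(chrom, pos)]
        var = truth.variants.iloc[vi]
        ref, alt = var["ref"], var["alt"]
        if var["vclass"] != "SNP":
            raise ValueError(f"locus {chrom}:{pos} is not a SNP")
        major = {
            s: (alt if truth.calls[vi, j] else ref)
            for j, s in enumerate(truth.substrains)
        }
        for s in pileup.substrains:
            counts = rec.loc[(chrom, pos, s), COUNT_COLUMNS].to_numpy(dtype=float)
            depth = counts.sum()
            pool_mates = [m for m in pileup.pools[pileup.pool_of(s)] if m != s]
            jump_bases = {major[m] for m in pool_mates if m in major} - {major[s]}
            focal = counts[base_idx[major[s]]]
            jump = sum(counts[base_idx[b]] for b in jump_bases)
            focal_freq = focal / depth if depth else 0.0
            jump_freq = jump / depth if depth else 0.0
            # complement of the rounded frequencies: per-cell conservation
            # focal + jump + error = 1 holds exactly in floating point
            error_freq = 1.0 - (focal_freq + jump_freq)
            rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "substrain": s,
                    "depth": int(depth),
                    "focal_freq": focal_freq,
                    "jump_freq": jump_freq,
                    "error_freq": error_freq,
                    "jump_informative": bool(jump_bases),
                }
            )
    cells = pd.DataFrame(rows)
    return ArtifactRates(cells=cells, n_loci_used=len(loci))
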