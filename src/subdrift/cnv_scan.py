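"""Deletion calling from ordered array-probe intensities.

Large deletions depress hybridization intensity over a *run* of consecutive
probes in the affected line only.  After per-probe centering (subtracting
the across-substrain median, so copy-neutral cells sit near 0), a deletion
is called as a maximal run of at least ``min_run`` consecutive probes whose
centered intensity falls below a negative ``threshold`` in one substrain.
Calls sharing an identical probe span across substrains are merged, which
is how a deletion shared by a subset of lines is reported as one event.

Probe arrays only bracket true breakpoints: a call's span is the first and
last probe of the run, not the base-pair breakpoints.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["IntensityTrack", "CnvCall", "scale_intensities", "call_deletions"]

META_COLUMNS = ["chrom", "pos"]


@dataclass
class IntensityTrack:
    """Ordered probes with one scaled-intensity column per substrain."""

    data: pd.DataFrame  # columns: chrom, pos, <substrain>...

    def __post_init__(self) -> None:
        for c in META_COLUMNS:
            if c not in self.data.columns:
                raise ValueError(f"intensity track missing column {c!r}")
        if self.data[self.substrains].isna().any().any():
            raise ValueError("intensity track has missing cells")
        for _, grp in self.data.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError("probe positions must strictly increase within a chromosome")

    @property
    def substrains(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IntensityTrack":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


@dataclass
class CnvCall:
    """One deletion call: an identical probe span in >=1 substrain."""

    chrom: str
    first_probe: int  # 1-based probe index within the chromosome
    last_probe: int   # 1-based, inclusive
    start_pos: int
    end_pos: int
    substrains: tuple[str, ...]
    mean_shift: float

    @property
    def n_probes(self) -> int:
        return self.last_probe - self.first_probe + 1

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "first_probe": self.first_probe,
            "last_probe": self.last_probe,
            "start_pos": self.start_pos,
            "end_pos": self.end_pos,
            "n_probes": self.n_probes,
            "substrains": list(self.substrains),
            "mean_shift": self.mean_shift,
        }


def scale_intensities(raw: IntensityTrack) -> IntensityTrack:
    """Center each probe by the across-substrain median.

    Copy-neutral cells land near 0 and a substrain-specific loss shows as a
    negative residual.  Median centering masks any shift shared by the
    majority of substrains, so a CNV common to most lines is invisible
    downstream (a warning notes this breakdown mode).
    """
    strains = raw.substrains
    if len(strains) < 2:
        raise ValueError("need at least 2 substrains to center intensities")
    if len(strains) < 3:
        warnings.warn("median centering with <3 substrains is degenerate", stacklevel=2)
    warnings.warn(
        "per-probe median centering masks CNVs shared by a majority of substrains",
        UserWarning,
        stacklevel=2,
    )
    mat = raw.data[strains].to_numpy(dtype=float)
    centered = mat - np.median(mat, axis=1, keepdims=True)
    out = raw.data[META_COLUMNS].copy()
    out[strains] = centered
    return IntensityTrack(out)


def _runs(mask: np.ndarray, min_run: int) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= min_run, as (start, stop) half-open."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start >= min_run:
                out.append((start, i))
            start = None
    if start is not None and len(mask) - start >= min_run:
        out.append((start, len(mask)))
    return out


def call_deletions(
    track: IntensityTrack,
    threshold: float = -0.5,
    min_run: int = 3,
    gains: bool = False,
) -> list[CnvCall]:
    """Call per-substrain deletion runs and merge identical spans.

    Parameters
    ----------
    track:
        Centered intensities (see :func:`scale_intensities`).
    threshold:
        Negative intensity cutoff; a probe cell participates in a run iff
        its value is strictly below it (default -0.5).
    min_run:
        Minimum number of consecutive probes (default 3): only long,
        multi-probe events are detectable on an array.
    gains:
        Also call duplications as runs *above* ``-threshold`` (off by
        default; losses are the primary signal).
    """
    if threshold >= 0:
        raise ValueError("threshold must be negative (deletion calling)")
    if min_run < 2:
        raise ValueError("min_run must be >= 2")

    grouped: dict[tuple[str, int, int], list[tuple[str, float]]] = {}
    for chrom, grp in track.data.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        for s in track.substrains:
            vals = grp[s].to_numpy(dtype=float)
            masks = [vals < threshold]
            if gains:
                masks.append(vals > -threshold)
            for mask in masks:
                for start, stop in _runs(mask, min_run):
                    keyd = (chrom, start, stop)
                    grouped.setdefault(keyd, []).append((s, float(vals[start:stop].mean())))

    calls = []
    for (chrom, start, stop), members in sorted(grouped.items()):
        grp = track.data[track.data["chrom"] == chrom]
        pos = grp["pos"].to_numpy()
        calls.append(
            CnvCall(
                chrom=chrom,
                first_probe=start + 1,
                last_probe=stop,
                start_pos=int(pos[start]),
                end_pos=int(pos[stop - 1]),
                substrains=tuple(sorted(s for s, _ in members)),
                mean_shift=float(np.mean([m for _, m in members])),
            )
        )
    return calls


def write_bed(calls: list[CnvCall], path: str | Path) -> None:
    """Write calls as BED (0-based half-open) with the substrain set in column 4."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.start_pos - 1}\t{c.end_pos}\t"
                f"{','.join(c.substrains)}\t{c.mean_shift:.4f}\n"
            )


def write_json_report(calls: list[CnvCall], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"calls": [c.to_dict() for c in calls]}, indent=2, sort_keys=True)
    )
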