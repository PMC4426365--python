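"""Pairwise fixed-difference distances and fixation-rate estimation.

Fully inbred substrains differ by *fixed differences*: sites where two
lines carry different homozygous alleles.  Counting them per pair yields a
symmetric Hamming distance matrix per variant class (SNP, indel, coding,
all); dividing a pair's coding count by its separation time gives the rate
at which coding polymorphisms fix per year (and, through the breeding
tempo, per generation).

The package ships the published five-substrain pairwise count matrices as a
fixture (:func:`load_reference_matrix`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable
from .schedule import SeparationSchedule

__all__ = [
    "DistanceMatrix",
    "RateEstimate",
    "pairwise_distance",
    "distance_summary",
    "sdp_table",
    "consequence_tally",
    "fixation_rate",
    "per_generation_range",
    "load_reference_matrix",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (reporting rule)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative integer fixed-difference counts."""

    labels: list[str]
    values: np.ndarray
    variant_class: str = "all"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.validate()

    def validate(self) -> None:
        n = len(self.labels)
        v = self.values
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.array_equal(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(v < 0):
            raise ValueError("distance matrix must be nonnegative")

    def __getitem__(self, pair: tuple[str, str]) -> int:
        i, j = (self.labels.index(x) for x in pair)
        return self.values[i, j]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path, variant_class: str = "all") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(), variant_class)


def load_reference_matrix(variant_class: str = "SNP") -> DistanceMatrix:
    """The packaged published pairwise count matrix (``SNP`` or ``indel``)."""
    name = {"SNP": "reference_snp_counts.tsv", "indel": "reference_indel_counts.tsv"}.get(variant_class)
    if name is None:
        raise ValueError(f"no packaged matrix for class {variant_class!r}")
    with resources.files("subdrift.data").joinpath(name).open() as fh:
        return DistanceMatrix.from_tsv(fh, variant_class)


# ----------------------------------------------------------------------
# distances
# ----------------------------------------------------------------------

def pairwise_distance(table: GenotypeTable, variant_class: str = "all") -> DistanceMatrix:
    """Count class-matching variants at which each pair differs."""
    mask = table.class_mask(variant_class)
    calls = table.calls[mask].astype(np.int64)
    n = table.n_substrains
    if calls.size:
        # Hamming counts: a != b at a site iff (a - b)^2 == 1 for 0/1 calls
        d = np.zeros((n, n), dtype=np.int64)
        for i in range(n):
            d[i] = np.sum(calls != calls[:, [i]], axis=0)
    else:
        d = np.zeros((n, n), dtype=np.int64)
    return DistanceMatrix(list(table.substrains), d, variant_class)


def distance_summary(
    m: DistanceMatrix,
) -> tuple[tuple[int, tuple[str, str]], tuple[int, tuple[str, str]]]:
    """Minimum and maximum off-diagonal entry with their (sorted) pairs.

    Ties are broken by lexicographic pair order.
    """
    if len(m.labels) < 2:
        raise ValueError("need at least 2 labels for a distance summary")
    pairs = sorted(tuple(sorted((a, b))) for a, b in combinations(m.labels, 2))
    min_val = min(m[p] for p in pairs)
    max_val = max(m[p] for p in pairs)
    best_min = next(p for p in pairs if m[p] == min_val)
    best_max = next(p for p in pairs if m[p] == max_val)
    return (int(min_val), best_min), (int(max_val), best_max)


# ----------------------------------------------------------------------
# substrain distribution patterns
# ----------------------------------------------------------------------

def sdp_table(table: GenotypeTable) -> pd.DataFrame:
    """Per-variant substrain distribution pattern (SDP).

    Returns a DataFrame with one row per variant: the carrier subset
    (comma-joined substrain names), its size, and flags for
    substrain-unique patterns (size 1), complement-unique patterns
    (size n-1 — unique up to the arbitrary polarity against the reference)
    and non-informative patterns (size 0 or n, which carry no pairwise
    signal and are excluded from distances).
    """
    n = table.n_substrains
    names = np.array(table.substrains)
    rows = []
    for i in range(len(table)):
        carriers = names[table.calls[i]]
        size = len(carriers)
        rows.append(
            {
                "chrom": table.variants.iloc[i]["chrom"],
                "pos": table.variants.iloc[i]["pos"],
                "vclass": table.variants.iloc[i]["vclass"],
                "sdp": ",".join(carriers),
                "n_carriers": size,
                "unique": size == 1,
                "complement_unique": size == n - 1,
                "informative": 0 < size < n,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "vclass", "sdp", "n_carriers",
            "unique", "complement_unique", "informative",
        ],
    )


def unique_variant_counts(table: GenotypeTable) -> dict[str, dict[str, int]]:
    """Per-substrain counts of size-1 and size-(n-1) SDPs."""
    sdp = sdp_table(table)
    out = {s: {"unique": 0, "complement_unique": 0} for s in table.substrains}
    names = set(table.substrains)
    for _, row in sdp.iterrows():
        carriers = set(row["sdp"].split(",")) if row["sdp"] else set()
        if row["unique"]:
            out[next(iter(carriers))]["unique"] += 1
        elif row["complement_unique"]:
            out[next(iter(names - carriers))]["complement_unique"] += 1
    return out


# ----------------------------------------------------------------------
# consequence tally
# ----------------------------------------------------------------------

def consequence_tally(table: GenotypeTable) -> pd.DataFrame:
    """Counts and percentages per consequence category, plus class totals.

    Variants without a consequence label are tallied as ``unannotated``.
    Returns a DataFrame with columns category, count, pct plus one
    ``total:<class>`` row per variant class and a ``total`` row;
    percentages (over categorized variants) sum to 100 within rounding.
    """
    labels = table.variants["consequence"].fillna("unannotated").replace("", "unannotated")
    counts = labels.value_counts()
    total = int(len(table))
    rows = [
        {"category": cat, "count": int(c), "pct": 100.0 * c / total if total else 0.0}
        for cat, c in sorted(counts.items())
    ]
    for vclass in ("SNP", "indel"):
        rows.append(
            {
                "category": f"total:{vclass}",
                "count": int(table.class_mask(vclass).sum()),
                "pct": np.nan,
            }
        )
    rows.append({"category": "total", "count": total, "pct": 100.0 if total else 0.0})
    return pd.DataFrame(rows, columns=["category", "count", "pct"])


# ----------------------------------------------------------------------
# fixation rate
# ----------------------------------------------------------------------

@dataclass
class RateEstimate:
    """Range of per-pair fixation rates, per year and per generation."""

    per_year_min: float
    per_year_max: float
    per_generation_min: float
    per_generation_max: float
    pairs_used: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.per_year_min > self.per_year_max:
            raise ValueError("min rate exceeds max rate")

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Reporting view, rounded half-up at ``ndigits`` decimals."""
        return {
            "per_year_min": round_half_up(self.per_year_min, ndigits),
            "per_year_max": round_half_up(self.per_year_max, ndigits),
            "per_generation_min": round_half_up(self.per_generation_min, ndigits),
            "per_generation_max": round_half_up(self.per_generation_max, ndigits),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "per_year_min": self.per_year_min,
                    "per_year_max": self.per_year_max,
                    "per_generation_min": self.per_generation_min,
                    "per_generation_max": self.per_generation_max,
                    "pairs_used": [list(p) for p in self.pairs_used],
                    "rounded": self.rounded(),
                },
                indent=2,
                sort_keys=True,
            )
        )


def fixation_rate(
    coding_distances: DistanceMatrix,
    schedule: SeparationSchedule,
    single_lineage: bool = False,
) -> RateEstimate:
    """Per-pair fixation rate range from coding distances and split dates.

    Each pair contributes ``distance / (2 x years since separation)`` —
    both lineages accumulate mutations over the separation interval —
    or ``distance / years`` when ``single_lineage`` is set.  The range
    endpoints are the extremes over pairs; per-generation endpoints divide
    by the schedule's generations/year.  Rounding is applied only at
    reporting (:meth:`RateEstimate.rounded`).
    """
    divisor = 1.0 if single_lineage else 2.0
    pairs = sorted(tuple(sorted(p)) for p in combinations(coding_distances.labels, 2))
    rates = {}
    for a, b in pairs:
        years = schedule.separation_years(a, b)
        if years <= 0:
            raise ValueError(f"non-positive separation time for pair ({a}, {b})")
        rates[(a, b)] = coding_distances[(a, b)] / (divisor * years)
    lo, hi = min(rates.values()), max(rates.values())
    g = schedule.generations_per_year
    return RateEstimate(
        per_year_min=lo,
        per_year_max=hi,
        per_generation_min=lo / g,
        per_generation_max=hi / g,
        pairs_used=pairs,
    )


def per_generation_range(
    per_year_min: float, per_year_max: float, generations_per_year: float = 4.0
) -> tuple[float, float]:
    """Convert a per-year rate range to per-generation, 2-dp half-up."""
    if generations_per_year <= 0:
        raise ValueError("generations_per_year must be > 0")
    return (
        round_half_up(per_year_min / generations_per_year),
        round_half_up(per_year_max / generations_per_year),
    )
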