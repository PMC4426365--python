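"""Synthetic data generators for every pipeline input.

Three generators mirror the statistical structure the analysis assumes:

* :func:`simulate_drift` — fixed-mutation accumulation along a dated
  substrain genealogy.  Sibling inbreeding fixes each new mutation to
  homozygosity, so drift is modeled as a Poisson process of *fixed*
  homozygous mutations per lineage per generation; a mutation arising on a
  branch is carried by exactly the tips below it, and heterozygous calls
  never occur.
* :func:`simulate_pooled_reads` — read pileups from pooled indexed capture
  libraries with a per-read per-base miscall probability ``e`` (uniform
  over the 3 alternative bases) and a per-read template-switching
  ("jumping PCR") probability ``j`` to a uniformly chosen other library in
  the same capture pool.
* :func:`simulate_intensities` — ordered array-probe intensity tracks with
  Gaussian noise and planted substrain-specific deletions (negative shifts).

All generators are bit-reproducible given their seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnv_scan import IntensityTrack
from .genotypes import GenotypeTable, VARIANT_COLUMNS
from .pool_artifacts import BASES, PileupCounts
from .schedule import SeparationSchedule

__all__ = [
    "DriftParams",
    "PoolDesign",
    "CnvSpec",
    "GenomeModel",
    "MM10_CHROM_SIZES",
    "DEFAULT_POOLS",
    "simulate_drift",
    "simulate_pooled_reads",
    "simulate_intensities",
]

#: approximate mm10 chromosome sizes (bp), 19 autosomes + X
MM10_CHROM_SIZES: dict[str, int] = {
    "1": 195_471_971, "2": 182_113_224, "3": 160_039_680, "4": 156_508_116,
    "5": 151_834_684, "6": 149_736_546, "7": 145_441_459, "8": 129_401_213,
    "9": 124_595_110, "10": 130_694_993, "11": 122_082_543, "12": 120_129_022,
    "13": 120_421_639, "14": 124_902_244, "15": 104_043_685, "16": 98_207_768,
    "17": 94_987_271, "18": 90_702_639, "19": 61_431_566, "X": 171_031_299,
}

#: capture pool design used throughout: three libraries pooled together,
#: the remaining two in a separate pool
DEFAULT_POOLS: dict[str, list[str]] = {
    "poolA": ["ShiLt", "ShiLtDvs", "MrkTac"],
    "poolB": ["BomTac", "ShiJcl"],
}

_CODING_SNP_LABELS = ("missense_variant", "synonymous_variant", "stop_gained")
_CODING_INDEL_LABELS = ("frameshift_variant", "inframe_deletion", "inframe_insertion")
_NONCODING_LABELS = (
    "intron_variant",
    "intergenic_variant",
    "3_prime_UTR_variant",
    "5_prime_UTR_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "splice_region_variant",
)


@dataclass
class GenomeModel:
    """Chromosome-length model from which variant positions are drawn."""

    chrom_sizes: dict[str, int] = field(default_factory=lambda: dict(MM10_CHROM_SIZES))

    def sample_positions(self, n: int, rng: np.random.Generator) -> list[tuple[str, int]]:
        """Draw ``n`` distinct (chrom, pos) uniformly, without replacement."""
        chroms = list(self.chrom_sizes)
        sizes = np.array([self.chrom_sizes[c] for c in chroms], dtype=float)
        p = sizes / sizes.sum()
        seen: set[tuple[str, int]] = set()
        out: list[tuple[str, int]] = []
        while len(out) < n:
            ci = rng.choice(len(chroms), p=p)
            pos = int(rng.integers(1, self.chrom_sizes[chroms[ci]] + 1))
            key = (chroms[ci], pos)
            if key not in seen:  # recurrent mutation disallowed
                seen.add(key)
                out.append(key)
        return out


@dataclass
class DriftParams:
    """Parameters of the fixed-mutation drift process.

    lambda_fix:
        Expected fixed mutations per lineage per generation over the
        surveyed target (default 0.3, which yields pairwise fixed-difference
        counts of the order seen between substrain colonies separated for
        two to three decades at 4 generations/year).
    coding_fraction / indel_fraction:
        Fractions of fixed mutations labeled coding / indel (defaults
        0.29 and 0.24, the proportions observed in a five-substrain exome
        screen: 66 coding of 227, 55 indels of 227).
    """

    lambda_fix: float = 0.3
    coding_fraction: float = 0.29
    indel_fraction: float = 0.24
    genome: GenomeModel = field(default_factory=GenomeModel)
    seed: int = 0

    def validate(self) -> None:
        if self.lambda_fix < 0:
            raise ValueError("lambda_fix must be >= 0")
        for name in ("coding_fraction", "indel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class PoolDesign:
    """Pooled-capture sequencing design.

    ``pools`` partitions the substrains into named capture pools;
    ``error_rate`` is the per-read per-base miscall probability and
    ``jump_rate`` the per-read probability of template switching to another
    in-pool library.  Defaults reflect a deep pooled exome capture:
    depth 200 reads/locus/strain, e = 0.05%, j = 1.6%.
    """

    pools: dict[str, list[str]] = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_POOLS.items()})
    depth_per_strain: int = 200
    error_rate: float = 0.0005
    jump_rate: float = 0.016
    seed: int = 0

    def validate(self, substrains: list[str] | None = None) -> None:
        members = [s for ms in self.pools.values() for s in ms]
        if len(members) != len(set(members)):
            raise ValueError("pools must be disjoint")
        if substrains is not None and set(members) != set(substrains):
            raise ValueError("pools must cover exactly the given substrains")
        if self.depth_per_strain < 1:
            raise ValueError("depth_per_strain must be >= 1")
        if self.error_rate < 0 or self.jump_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.error_rate + self.jump_rate > 1:
            raise ValueError("error_rate + jump_rate must be <= 1")

    def pool_of(self, substrain: str) -> str:
        for name, members in self.pools.items():
            if substrain in members:
                return name
        raise KeyError(f"substrain {substrain!r} not in any pool")


@dataclass
class CnvSpec:
    """Planted-deletion intensity-track specification.

    ``deletions`` is a list of ``(substrain set, (start, stop) half-open
    probe index range, shift delta < 0)``.
    """

    n_probes: int = 100
    probe_positions: list[int] | None = None
    chrom: str = "11"
    deletions: list[tuple[frozenset | set | list, tuple[int, int], float]] = field(default_factory=list)
    noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.probe_positions is not None:
            pos = np.asarray(self.probe_positions)
            if len(pos) != self.n_probes:
                raise ValueError("probe_positions length must equal n_probes")
            if not (np.diff(pos) > 0).all():
                raise ValueError("probe_positions must strictly increase")
        for strains, (start, stop), delta in self.deletions:
            if not (0 <= start < stop <= self.n_probes):
                raise ValueError(f"deletion range ({start}, {stop}) outside [0, {self.n_probes})")
            if delta >= 0:
                raise ValueError("deletion intensity shift must be negative")


# ----------------------------------------------------------------------
# drift
# ----------------------------------------------------------------------

def simulate_drift(
    schedule: SeparationSchedule, params: DriftParams
) -> tuple[GenotypeTable, dict[frozenset, tuple[float, int]]]:
    """Simulate fixed-mutation accumulation along the genealogy.

    Each branch of the dated tree accrues ``Poisson(lambda_fix * length in
    generations)`` mutations; every mutation is carried, homozygous, by
    exactly the tip substrains below its branch.

    Returns
    -------
    table:
        The resulting :class:`GenotypeTable` (variants in simulation order).
    truth:
        ``{tip set below branch: (branch length in generations, mutation
        count)}`` — the per-branch ground truth, for oracle checks.
    """
    params.validate()
    schedule.validate()
    tips = schedule.substrain_names
    if len(tips) < 2:
        raise ValueError("schedule must have at least 2 tips")
    rng = np.random.default_rng(params.seed)

    branches = list(schedule.branches())
    counts = [int(rng.poisson(params.lambda_fix * gens)) for _, gens in branches]
    total = int(sum(counts))
    positions = params.genome.sample_positions(total, rng)

    rows, call_rows = [], []
    truth: dict[frozenset, tuple[float, int]] = {}
    k = 0
    for (tipset, gens), n_mut in zip(branches, counts):
        truth[tipset] = (gens, n_mut)
        carried = np.array([t in tipset for t in tips])
        for _ in range(n_mut):
            chrom, pos = positions[k]
            k += 1
            is_indel = rng.random() < params.indel_fraction
            is_coding = rng.random() < params.coding_fraction
            ref_base = BASES[rng.integers(0, 4)]
            if is_indel:
                if rng.random() < 0.5:  # deletion
                    extra = "".join(BASES[i] for i in rng.integers(0, 4, size=int(rng.integers(1, 4))))
                    ref, alt = ref_base + extra, ref_base
                else:  # insertion
                    extra = "".join(BASES[i] for i in rng.integers(0, 4, size=int(rng.integers(1, 4))))
                    ref, alt = ref_base, ref_base + extra
                label_pool = _CODING_INDEL_LABELS if is_coding else _NONCODING_LABELS
            else:
                alt = BASES[(BASES.index(ref_base) + 1 + int(rng.integers(0, 3))) % 4]
                ref = ref_base
                label_pool = _CODING_SNP_LABELS if is_coding else _NONCODING_LABELS
            rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "vclass": "indel" if is_indel else "SNP",
                    "consequence": label_pool[int(rng.integers(0, len(label_pool)))],
                    "coding": is_coding,
                }
            )
            call_rows.append(carried)

    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    calls = (
        np.array(call_rows, dtype=bool) if call_rows else np.zeros((0, len(tips)), dtype=bool)
    )
    return GenotypeTable(variants, calls, tips), truth


# ----------------------------------------------------------------------
# pooled reads
# ----------------------------------------------------------------------

def simulate_pooled_reads(
    truth: GenotypeTable,
    loci: list[int] | np.ndarray,
    design: PoolDesign,
) -> PileupCounts:
    """Simulate read pileups for pooled indexed libraries at SNP loci.

    For each read from substrain ``s`` at a locus: with probability ``j``
    the emitted base is the true allele of a uniformly chosen other
    substrain in ``s``'s pool; otherwise, with probability ``e``, a
    uniformly chosen base other than ``s``'s allele; otherwise ``s``'s own
    allele.  Counts are drawn as one multinomial per (locus, substrain), so
    per-cell totals equal ``depth_per_strain`` exactly.
    """
    design.validate(truth.substrains)
    rng = np.random.default_rng(design.seed)
    e, j = design.error_rate, design.jump_rate
    base_idx = {b: k for k, b in enumerate(BASES)}

    rows = []
    for li in loci:
        var = truth.variants.iloc[int(li)]
        if var["vclass"] != "SNP":
            raise ValueError(f"locus index {li} is not a SNP")
        chrom, pos = var["chrom"], int(var["pos"])
        allele = {
            s: (var["alt"] if truth.calls[int(li), k] else var["ref"])
            for k, s in enumerate(truth.substrains)
        }
        for s in truth.substrains:
            mates = [m for m in design.pools[design.pool_of(s)] if m != s]
            p = np.zeros(4)
            own = base_idx[allele[s]]
            if mates:
                for m in mates:
                    p[base_idx[allele[m]]] += j / len(mates)
            else:
                p[own] += j  # no in-pool partner: no template to switch to
            for b in range(4):
                p[b] += (1.0 - j) * (e / 3.0 if b != own else 1.0 - e)
            counts = rng.multinomial(design.depth_per_strain, p)
            rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "substrain": s,
                    "count_A": int(counts[0]),
                    "count_C": int(counts[1]),
                    "count_G": int(counts[2]),
                    "count_T": int(counts[3]),
                }
            )
    columns = ["chrom", "pos", "substrain", "count_A", "count_C", "count_G", "count_T"]
    return PileupCounts(
        pd.DataFrame(rows, columns=columns),
        pools={k: list(v) for k, v in design.pools.items()},
    )


# ----------------------------------------------------------------------
# intensities
# ----------------------------------------------------------------------

def simulate_intensities(spec: CnvSpec, substrains: list[str]) -> IntensityTrack:
    """Simulate a centered probe-intensity track with planted deletions.

    Baseline cells are ``Normal(0, noise_sd)``; each planted deletion
    shifts its (substrain, probe) cells by its negative delta.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if spec.probe_positions is not None:
        pos = np.asarray(spec.probe_positions, dtype=int)
    else:
        step = 1000
        pos = np.arange(1, spec.n_probes + 1) * step
    mat = rng.normal(0.0, spec.noise_sd, size=(spec.n_probes, len(substrains)))
    for strains, (start, stop), delta in spec.deletions:
        for s in strains:
            jx = substrains.index(s)
            mat[start:stop, jx] += delta
    df = pd.DataFrame({"chrom": spec.chrom, "pos": pos})
    for k, s in enumerate(substrains):
        df[s] = mat[:, k]
    return IntensityTrack(df)
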