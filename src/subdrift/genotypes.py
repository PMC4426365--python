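"""Homozygous multi-substrain genotype tables.

Fully inbred lines carry one homozygous allele per site, so a call set
reduces to a variants x substrains boolean matrix (False = reference allele,
True = alternate allele).  Variants are classed as SNP (both alleles length
1) or indel, and may carry a free-text functional-consequence label plus a
coding flag.

I/O formats: a minimal VCF 4.2 dialect (CHROM, POS 1-based, REF, ALT, one
sample column per substrain, GT only, all calls homozygous) and a flat TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

__all__ = ["GenotypeTable", "LoadReport", "load_calls"]

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "vclass", "consequence", "coding"]

#: consequence labels counted as coding by default
DEFAULT_CODING_SET = frozenset(
    {
        "missense_variant",
        "synonymous_variant",
        "stop_gained",
        "stop_lost",
        "frameshift_variant",
        "inframe_insertion",
        "inframe_deletion",
    }
)


def classify_alleles(ref: str, alt: str) -> str:
    """SNP iff both alleles are single bases, otherwise indel."""
    return "SNP" if len(ref) == 1 and len(alt) == 1 else "indel"


@dataclass
class LoadReport:
    """Bookkeeping for VCF ingestion: records kept vs dropped."""

    kept: int
    dropped: int

    @property
    def total(self) -> int:
        return self.kept + self.dropped


class GenotypeTable:
    """Variants x substrains homozygous allele calls.

    Parameters
    ----------
    variants:
        DataFrame with columns ``chrom, pos, ref, alt, vclass`` and optional
        ``consequence`` (str or None) and ``coding`` (bool).
    calls:
        Boolean array of shape ``(n_variants, n_substrains)``; True means
        the substrain carries the alternate allele (homozygous).
    substrains:
        Column labels for ``calls``.
    """

    def __init__(self, variants: pd.DataFrame, calls: np.ndarray, substrains: list[str]):
        variants = variants.reset_index(drop=True).copy()
        if "consequence" not in variants.columns:
            variants["consequence"] = None
        if "coding" not in variants.columns:
            variants["coding"] = False
        if "vclass" not in variants.columns:
            variants["vclass"] = [
                classify_alleles(r, a) for r, a in zip(variants["ref"], variants["alt"])
            ]
        calls = np.asarray(calls, dtype=bool)
        if calls.shape != (len(variants), len(substrains)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(variants)} variants x {len(substrains)} substrains"
            )
        for ref, alt, vclass in zip(variants["ref"], variants["alt"], variants["vclass"]):
            if classify_alleles(ref, alt) != vclass:
                raise ValueError(f"class {vclass!r} inconsistent with alleles {ref}>{alt}")
        self.variants = variants
        self.calls = calls
        self.substrains = list(substrains)

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.variants)

    @property
    def n_substrains(self) -> int:
        return len(self.substrains)

    def class_mask(self, variant_class: str) -> np.ndarray:
        """Boolean row mask for ``SNP``, ``indel``, ``coding`` or ``all``."""
        if variant_class == "all":
            return np.ones(len(self), dtype=bool)
        if variant_class in ("SNP", "indel"):
            return (self.variants["vclass"] == variant_class).to_numpy()
        if variant_class == "coding":
            return self.variants["coding"].fillna(False).to_numpy(dtype=bool)
        raise ValueError(f"unknown variant class {variant_class!r}")

    def subset(self, mask: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(self.variants[mask], self.calls[mask], self.substrains)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        a = self.variants[VARIANT_COLUMNS].fillna("")
        b = other.variants[VARIANT_COLUMNS].fillna("")
        return (
            self.substrains == other.substrains
            and a.reset_index(drop=True).equals(b.reset_index(drop=True))
            and np.array_equal(self.calls, other.calls)
        )

    # ------------------------------------------------------------------
    # TSV
    # ------------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        df = self.variants[VARIANT_COLUMNS].copy()
        for i, s in enumerate(self.substrains):
            df[s] = np.where(self.calls[:, i], "alt", "ref")
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        substrains = [c for c in df.columns if c not in VARIANT_COLUMNS]
        calls = (df[substrains] == "alt").to_numpy()
        variants = df[VARIANT_COLUMNS].copy()
        variants["consequence"] = variants["consequence"].where(
            variants["consequence"].notna(), None
        )
        return cls(variants, calls, substrains)

    # ------------------------------------------------------------------
    # minimal VCF
    # ------------------------------------------------------------------
    def to_vcf(self, path: str | Path) -> None:
        """Write the minimal VCF 4.2 dialect (GT-only, all homozygous)."""
        order = np.lexsort(
            (self.variants["pos"].to_numpy(), self.variants["chrom"].to_numpy())
        )
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence label">\n'
            )
            for chrom in pd.unique(self.variants["chrom"].to_numpy()[order]):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.substrains)
                + "\n"
            )
            for i in order:
                row = self.variants.iloc[i]
                csq = row["consequence"]
                info = f"CSQ={csq}" if csq else "."
                gts = ["1/1" if x else "0/0" for x in self.calls[i]]
                fh.write(
                    f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}\t"
                    f".\t.\t{info}\tGT\t" + "\t".join(gts) + "\n"
                )


def load_calls(
    vcf_path: str | Path,
    substrains: list[str] | None = None,
    coding_set: frozenset = DEFAULT_CODING_SET,
) -> tuple[GenotypeTable, LoadReport]:
    """Load homozygous calls from a VCF, dropping het/missing records.

    Records with any heterozygous or missing genotype across the requested
    substrains are dropped and counted in the returned :class:`LoadReport`.
    Multi-allelic records are split into one biallelic row per alternate
    allele (a substrain is True for the row matching its allele).

    Raises
    ------
    KeyError
        If a requested substrain has no sample column.
    ValueError
        If the file cannot be parsed as VCF.
    """
    try:
        vf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {vcf_path}: {exc}") from exc
    with vf:
        available = list(vf.header.samples)
        if substrains is None:
            substrains = available
        missing = [s for s in substrains if s not in available]
        if missing:
            raise KeyError(f"substrain column(s) not in VCF: {missing}")

        rows, call_rows = [], []
        dropped = 0
        for rec in vf:
            gts = []
            ok = True
            for s in substrains:
                alleles = rec.samples[s]["GT"]
                if (
                    alleles is None
                    or any(a is None for a in alleles)
                    or len(set(alleles)) != 1
                ):
                    ok = False
                    break
                gts.append(alleles[0])
            if not ok:
                dropped += 1
                continue
            csq = rec.info.get("CSQ") if "CSQ" in rec.info else None
            if isinstance(csq, tuple):
                csq = csq[0]
            for ai, alt in enumerate(rec.alts or (), start=1):
                carried = np.array([g == ai for g in gts])
                rows.append(
                    {
                        "chrom": rec.chrom,
                        "pos": rec.pos,
                        "ref": rec.ref,
                        "alt": alt,
                        "vclass": classify_alleles(rec.ref, alt),
                        "consequence": csq,
                        "coding": csq in coding_set if csq else False,
                    }
                )
                call_rows.append(carried)

    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    calls = (
        np.array(call_rows, dtype=bool)
        if call_rows
        else np.zeros((0, len(substrains)), dtype=bool)
    )
    return GenotypeTable(variants, calls, list(substrains)), LoadReport(
        kept=len(variants), dropped=dropped
    )
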