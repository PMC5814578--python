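"""Genotype-matrix construction from multi-sample VCF.

Downstream statistics (pooled similarity, windowed FST, p-distance trees)
are all defined on a complete, biallelic, homozygous SNV panel: every
accession carries exactly one allele per retained site, so diploid
homozygous calls collapse to a single haploid code (0 = ref, 1 = alt).
This module ingests a VCF, applies site-quality filters (mapping quality,
read depth), drops multiallelic / heterozygous / incomplete sites and
returns the resulting matrix together with a per-reason drop report whose
counts reconcile exactly with the number of input sites.

Positions are converted once, on ingestion, from VCF 1-based to 0-based
half-open coordinates; exporters convert back per format convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "VariantSite",
    "GroupSpec",
    "GenotypeMatrix",
    "read_group_spec",
    "read_vcf",
    "filter_site",
    "build_matrix",
    "matrix_from_vcf",
]

SITE_COLUMNS = ("chrom", "pos", "ref", "alt")


@dataclass
class VariantSite:
    """One VCF record: diploid genotype calls plus site/sample quality.

    ``pos`` is the 1-based VCF position.  ``genotypes`` holds one
    allele-index pair per sample; ``None`` inside a pair marks a missing
    allele.  ``depths`` is the per-sample read depth (``None`` when the
    FORMAT field is absent).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    genotypes: list[tuple[Optional[int], Optional[int]]]
    mapping_quality: Optional[float] = None
    depths: Optional[list[Optional[int]]] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        n_alleles = 1 + len(self.alt_alleles)
        for pair in self.genotypes:
            for a in pair:
                if a is not None and not (0 <= a < n_alleles):
                    raise ValueError(
                        f"allele index {a} out of range at {self.chrom}:{self.pos}"
                    )


@dataclass
class GroupSpec:
    """Named partition of sample ids into analysis groups (e.g. MCB, QK)."""

    groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("GroupSpec requires at least one group")
        seen: dict[str, str] = {}
        for name, members in self.groups.items():
            if not members:
                raise ValueError(f"group {name!r} is empty")
            for sample in members:
                if sample in seen:
                    raise ValueError(
                        f"sample {sample!r} listed in both {seen[sample]!r} and {name!r}"
                    )
                seen[sample] = name

    @property
    def samples(self) -> list[str]:
        """All sample ids, in group order then within-group order."""
        return [s for members in self.groups.values() for s in members]

    def sizes(self) -> dict[str, int]:
        return {g: len(m) for g, m in self.groups.items()}

    def group_of(self, sample: str) -> str:
        for g, members in self.groups.items():
            if sample in members:
                return g
        raise KeyError(sample)


@dataclass
class GenotypeMatrix:
    """Samples x sites haploid allele codes over a complete biallelic panel.

    ``sites`` has columns (chrom, pos, ref, alt) with pos 0-based;
    ``calls`` is uint8 of shape (n_samples, n_sites) with 0 = ref, 1 = alt.
    """

    samples: list[str]
    sites: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        if list(self.sites.columns[:4]) != list(SITE_COLUMNS):
            raise ValueError(f"sites must have columns {SITE_COLUMNS}")
        self.calls = np.asarray(self.calls, dtype=np.uint8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        if self.calls.size and self.calls.max() > 1:
            raise ValueError("calls must be haploid codes in {0, 1}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.sites["chrom"]))

    def sample_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in matrix") from None

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero((self.sites["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def to_tsv(self, path: str | Path, drop_report: Optional[dict] = None) -> None:
        """Write sites x samples TSV (pos back to 1-based) plus an optional
        sidecar JSON drop report at ``<path>.drops.json``."""
        out = self.sites.copy()
        out["pos"] = out["pos"] + 1
        for i, s in enumerate(self.samples):
            out[s] = self.calls[i]
        out.to_csv(path, sep="\t", index=False)
        if drop_report is not None:
            Path(str(path) + ".drops.json").write_text(
                json.dumps(drop_report, indent=2) + "\n"
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        samples = [c for c in df.columns if c not in SITE_COLUMNS]
        sites = df[list(SITE_COLUMNS)].copy()
        sites["pos"] = sites["pos"] - 1
        calls = df[samples].to_numpy(dtype=np.uint8).T
        return cls(samples=samples, sites=sites, calls=calls)


def read_group_spec(path: str | Path) -> GroupSpec:
    """Read a two-column sample<TAB>group table, preserving group order."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns, found {df.shape[1]}")
    groups: dict[str, list[str]] = {}
    for sample, group in df.itertuples(index=False):
        groups.setdefault(group, []).append(sample)
    return GroupSpec(groups)


def filter_site(
    site: VariantSite,
    min_mq: float = 25,
    min_depth: int = 3,
    depth_mode: str = "per_sample",
) -> bool:
    """Site-quality predicate: mapping quality >= min_mq and read depth
    >= min_depth (the conventional "coverage > min_depth - 1").

    ``depth_mode='per_sample'`` requires every sample with a called
    genotype to meet the depth floor (the default: downstream stages need
    complete genotypes); ``'pooled'`` applies the floor to summed depth.
    Sites without quality annotations pass the corresponding check.
    """
    if min_mq < 0 or min_depth < 0:
        raise ValueError("thresholds must be >= 0")
    if site.mapping_quality is not None and site.mapping_quality < min_mq:
        return False
    if site.depths is None:
        return True
    if depth_mode == "per_sample":
        for pair, dp in zip(site.genotypes, site.depths):
            called = any(a is not None for a in pair)
            if called and dp is not None and dp < min_depth:
                return False
        return True
    if depth_mode == "pooled":
        total = sum(d for d in site.depths if d is not None)
        return total >= min_depth
    raise ValueError(f"unknown depth_mode {depth_mode!r}")


def read_vcf(
    path: str | Path,
    mq_tag: str = "MQ",
    dp_tag: str = "DP",
) -> Iterator[VariantSite]:
    """Stream VariantSite records from a VCF (plain or bgzip).

    Mapping quality is taken from INFO[mq_tag]; per-sample depth from
    FORMAT[dp_tag]. Either may be absent, leaving the field None.
    """
    with pysam.VariantFile(str(path)) as vcf:
        sample_ids = list(vcf.header.samples)
        for rec in vcf:
            genotypes = []
            depths = []
            any_depth = False
            for s in sample_ids:
                call = rec.samples[s]
                gt = call.get("GT", (None, None))
                if gt is None:
                    gt = (None, None)
                if len(gt) == 1:  # haploid record: duplicate the allele
                    gt = (gt[0], gt[0])
                genotypes.append((gt[0], gt[1]))
                dp = call.get(dp_tag, None)
                if dp is not None:
                    any_depth = True
                depths.append(dp)
            mq = rec.info.get(mq_tag, None)
            yield VariantSite(
                chrom=rec.chrom,
                pos=rec.pos,
                ref_allele=rec.ref,
                alt_alleles=tuple(rec.alts or ()),
                genotypes=genotypes,
                mapping_quality=float(mq) if mq is not None else None,
                depths=depths if any_depth else None,
            )


def vcf_samples(path: str | Path) -> list[str]:
    with pysam.VariantFile(str(path)) as vcf:
        return list(vcf.header.samples)


def build_matrix(
    sites: Iterable[VariantSite],
    spec: GroupSpec,
    sample_ids: Optional[Sequence[str]] = None,
    drop_report: Optional[dict[str, int]] = None,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Build the haploid genotype matrix from a sorted stream of sites.

    Retains only sites that are biallelic SNVs, fully called, and
    homozygous in every sample listed in ``spec``; homozygous diploid
    calls collapse to one haploid code.  ``sample_ids`` gives the column
    order of the genotype pairs in each site (defaults to spec order).
    Returns (matrix, drop_report); retained + sum(drops) = input count.
    """
    report = drop_report if drop_report is not None else {}
    for key in ("multiallelic", "missing", "het"):
        report.setdefault(key, 0)
    report.setdefault("retained", 0)

    wanted = spec.samples
    if sample_ids is None:
        take = list(range(len(wanted)))
    else:
        lookup = {s: i for i, s in enumerate(sample_ids)}
        missing = [s for s in wanted if s not in lookup]
        if missing:
            raise ValueError(f"samples absent from VCF header: {missing}")
        take = [lookup[s] for s in wanted]

    chrom_order: list[str] = []
    last_pos = -1
    rows: list[tuple[str, int, str, str]] = []
    codes: list[np.ndarray] = []
    for site in sites:
        if not chrom_order or site.chrom != chrom_order[-1]:
            if site.chrom in chrom_order:
                raise ValueError(
                    f"input not sorted: chromosome {site.chrom} re-appears"
                )
            chrom_order.append(site.chrom)
            last_pos = -1
        if site.pos < last_pos:
            raise ValueError(
                f"input not sorted at {site.chrom}:{site.pos} (after {last_pos})"
            )
        last_pos = site.pos

        if len(site.alt_alleles) != 1 or len(site.ref_allele) != 1 or len(
            site.alt_alleles[0]
        ) != 1:
            report["multiallelic"] += 1
            continue
        gts = [site.genotypes[i] for i in take]
        if any(a is None for pair in gts for a in pair):
            report["missing"] += 1
            continue
        if any(pair[0] != pair[1] for pair in gts):
            report["het"] += 1
            continue
        rows.append((site.chrom, site.pos - 1, site.ref_allele, site.alt_alleles[0]))
        codes.append(np.fromiter((pair[0] for pair in gts), dtype=np.uint8))

    report["retained"] += len(rows)
    sites_df = pd.DataFrame(rows, columns=list(SITE_COLUMNS))
    if codes:
        calls = np.stack(codes, axis=1)
    else:
        calls = np.zeros((len(wanted), 0), dtype=np.uint8)
    return GenotypeMatrix(samples=wanted, sites=sites_df, calls=calls), report


def matrix_from_vcf(
    path: str | Path,
    spec: GroupSpec,
    min_mq: float = 25,
    min_depth: int = 3,
    depth_mode: str = "per_sample",
    mq_tag: str = "MQ",
    dp_tag: str = "DP",
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """VCF -> quality filters -> genotype matrix, with a full drop report.

    Report keys: low_mq_or_depth, multiallelic, missing, het, retained;
    their sum equals the number of VCF records read.
    """
    report = {"low_mq_or_depth": 0}

    def passing() -> Iterator[VariantSite]:
        for site in read_vcf(path, mq_tag=mq_tag, dp_tag=dp_tag):
            if filter_site(site, min_mq=min_mq, min_depth=min_depth,
                           depth_mode=depth_mode):
                yield site
            else:
                report["low_mq_or_depth"] += 1

    matrix, report = build_matrix(
        passing(), spec, sample_ids=vcf_samples(path), drop_report=report
    )
    return matrix, report
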