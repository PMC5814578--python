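"""Windowed Weir & Cockerham FST scan for selective sweeps.

The fixation index between two groups is estimated per site with the
Weir & Cockerham (1984) variance components for two populations; on a
fully homozygous panel the observed heterozygosity is identically zero,
which is exactly the full-inbreeding case the observed-het terms of the
estimator are designed to absorb.  Window values are the ratio of summed
numerators to summed denominators ("weighted" FST), not the mean of
per-site ratios.  Windows above a threshold — either the empirical top
fraction of defined window values or a fixed cut — are merged into sweep
regions, and annotated genes overlapping any region by at least 1 bp are
reported.

Negative per-site and per-window estimates are kept as computed (the
estimator is unbiased around 0 for undifferentiated groups); windows
whose denominator sum is 0 are undefined (NaN) and excluded from the
empirical threshold by default.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .similarity import PoolFrequencies, _window_site_ranges

__all__ = [
    "site_fst_components",
    "window_fst",
    "empirical_threshold",
    "call_sweeps",
    "genes_in_sweeps",
    "read_bed",
    "read_gff3",
]


def site_fst_components(n1, p1, n2, p2, ploidy: int = 2):
    """Weir & Cockerham (1984) two-population variance components at
    biallelic sites with observed heterozygosity 0.

    ``n1``/``n2`` are sample counts per group and ``p1``/``p2`` the
    groups' alt-allele frequencies; scalars or site-length arrays.  With
    ``ploidy=2`` (default) each sample is a diploid individual carrying
    two identical alleles, matching standard VCF-based tools on a
    homozygous panel; ``ploidy=1`` treats each count as one haploid
    allele.  On this panel the two conventions use the same component
    algebra because every quality term involving heterozygosity is zero.

    Returns ``(a, d)`` where ``a`` is the among-population component and
    ``d = a + b + c`` the total; the site estimate is ``a / d``.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("need at least 2 samples per group")
    for p in (p1, p2):
        if p.size and (np.min(p) < 0 or np.max(p) > 1):
            raise ValueError("allele frequencies must lie in [0, 1]")
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")

    r = 2.0
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = 0.0  # homozygous panel: no observed heterozygotes
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - s2 * (r - 1) / r
        - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = np.zeros_like(a) + hbar / 2
    return a, a + b + c


def pair_components(
    freqs: PoolFrequencies, g1: str, g2: str, ploidy: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site W&C components between two named pools."""
    return site_fst_components(
        freqs.n[g1], freqs.freq(g1), freqs.n[g2], freqs.freq(g2), ploidy=ploidy
    )


def window_fst(
    sites: pd.DataFrame,
    a: np.ndarray,
    d: np.ndarray,
    windows: pd.DataFrame,
) -> pd.DataFrame:
    """Weighted window FST: sum(a) / sum(a+b+c) over the sites in each
    window.  Windows whose denominator sum is 0 (e.g. no SNVs) get NaN.
    Returns (chrom, start, end, n_snvs, fst)."""
    a = np.asarray(a, dtype=float)
    d = np.asarray(d, dtype=float)
    if a.shape != d.shape or len(a) != len(sites):
        raise ValueError("component arrays must match the site table")
    i0, i1 = _window_site_ranges(sites, windows)
    ca = np.concatenate([[0.0], np.cumsum(a)])
    cd = np.concatenate([[0.0], np.cumsum(d)])
    num = ca[i1] - ca[i0]
    den = cd[i1] - cd[i0]
    out = windows[["chrom", "start", "end"]].copy()
    out["n_snvs"] = (i1 - i0).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["fst"] = np.where(den != 0, num / den, np.nan)
    return out


def empirical_threshold(fst_values, top_frac: float = 0.05) -> float:
    """The (1 - top_frac) quantile (linear interpolation) of the defined
    window FST values; values above it form the empirical top fraction."""
    v = np.asarray(fst_values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no defined FST values")
    if not 0 < top_frac < 1:
        raise ValueError("top_frac must lie in (0, 1)")
    return float(np.quantile(v, 1 - top_frac))


def merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Merge sorted [start, end) intervals that overlap or book-end."""
    if len(iv) == 0:
        return iv.reshape(0, 2)
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged)


def call_sweeps(
    fst_windows: pd.DataFrame,
    threshold: float,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge windows with fst > threshold into sweep regions.

    Returns ``(regions, fractions)``: regions have (chrom, start, end,
    peak_fst, n_windows); fractions give merged sweep length and the
    fraction of each chromosome (and the genome) under sweeps, using
    ``chrom_lengths`` when provided, else the span covered by windows.
    """
    passing = fst_windows[fst_windows["fst"] > threshold]
    region_rows = []
    length_by_chrom: dict[str, int] = {}
    for chrom in dict.fromkeys(fst_windows["chrom"]):
        sub = passing[passing["chrom"] == chrom]
        sub = sub.sort_values("start", kind="stable")
        merged = merge_intervals(sub[["start", "end"]].to_numpy())
        for s, e in merged:
            members = sub[(sub["start"] < e) & (sub["end"] > s)]
            region_rows.append(
                (chrom, int(s), int(e), float(members["fst"].max()), len(members))
            )
        length_by_chrom[chrom] = int(merged[:, 1].sum() - merged[:, 0].sum()) if len(merged) else 0
    regions = pd.DataFrame(
        region_rows, columns=["chrom", "start", "end", "peak_fst", "n_windows"]
    )

    frac_rows = []
    total_sweep = 0
    total_len = 0
    for chrom in dict.fromkeys(fst_windows["chrom"]):
        if chrom_lengths is not None:
            clen = chrom_lengths[chrom]
        else:
            clen = int(fst_windows.loc[fst_windows["chrom"] == chrom, "end"].max())
        swept = length_by_chrom.get(chrom, 0)
        frac_rows.append((chrom, swept, clen, swept / clen))
        total_sweep += swept
        total_len += clen
    frac_rows.append(("genome", total_sweep, total_len,
                      total_sweep / total_len if total_len else 0.0))
    fractions = pd.DataFrame(
        frac_rows, columns=["chrom", "sweep_length", "total_length", "fraction"]
    )
    return regions, fractions


def genes_in_sweeps(
    regions: pd.DataFrame, genes: pd.DataFrame
) -> tuple[list[str], float]:
    """Genes overlapping any sweep region by >= 1 bp, each counted once.

    ``genes`` needs columns (chrom, start, end, gene_id) with 0-based
    half-open coordinates.  Returns (gene id list in input order,
    fraction of all genes hit)."""
    required = {"chrom", "start", "end", "gene_id"}
    if not required.issubset(genes.columns):
        raise ValueError(f"gene table needs columns {sorted(required)}")
    hits: list[str] = []
    by_chrom = {}
    for chrom, sub in regions.groupby("chrom", sort=False):
        sub = sub.sort_values("start", kind="stable")
        by_chrom[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy())
    for chrom, s, e, gid in genes[["chrom", "start", "end", "gene_id"]].itertuples(
        index=False
    ):
        if e <= s:
            raise ValueError(f"malformed interval for gene {gid!r}: [{s}, {e})")
        if chrom not in by_chrom:
            continue
        starts, ends = by_chrom[chrom]
        # first region whose end is beyond the gene start
        i = int(np.searchsorted(ends, s, side="right"))
        if i < len(starts) and starts[i] < e:
            hits.append(gid)
    fraction = len(hits) / len(genes) if len(genes) else 0.0
    return hits, fraction


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file of gene intervals -> (chrom, start, end, gene_id)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates")
            if end <= start or start < 0:
                raise ValueError(f"{path}:{lineno}: invalid interval {start}-{end}")
            name = fields[3] if len(fields) > 3 else f"feature_{lineno}"
            rows.append((fields[0], start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def read_gff3(path: str | Path, feature_type: str = "gene") -> pd.DataFrame:
    """Read gene intervals from GFF3 (1-based closed -> 0-based half-open)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if fields[2] != feature_type:
                continue
            try:
                start, end = int(fields[3]) - 1, int(fields[4])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: invalid interval")
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            rows.append((fields[0], start, end, attrs.get("ID", f"feature_{lineno}")))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])
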