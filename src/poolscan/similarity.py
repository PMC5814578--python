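"""Pooled-group sliding-window genomic similarity.

Each analysis group is collapsed into a gene pool: the per-site alternate
allele frequency over its members.  Overlapping windows (default 500 kb,
250-kb step) are then scored for similarity between a focal pool and every
other pool; windows with enough SNVs (>= 25) and a high enough best
similarity (>= 0.95) qualify and are assigned uniquely to the arg-max
group.  Per-chromosome similarity percentages are computed from the total
nominal length of windows assigned to each group.

The per-site similarity between two pools with alt frequencies p1, p2 is
1 - |p1 - p2| (method ``"freq"``): it is symmetric, bounded in [0, 1],
and reduces to consensus-allele identity when both pools are fixed.  A
major-allele-match variant (method ``"major"``: 1 when the pools' majority
alleles agree, 0 when they disagree, 0.5 credit when either pool sits at
exactly 0.5) is available as a configuration switch.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .snv_matrix import GenotypeMatrix, GroupSpec

__all__ = [
    "PoolFrequencies",
    "make_windows",
    "pool_allele_frequencies",
    "site_similarity",
    "window_scan",
    "assign_unique_windows",
    "summarize_similarity",
    "export_links",
    "read_links",
]

SIMILARITY_METHODS = ("freq", "major")


@dataclass
class PoolFrequencies:
    """Per-group per-site alt-allele frequencies over a shared site table.

    ``p`` has shape (n_groups, n_sites); ``n`` maps group -> haploid
    sample count (equal to group size: the matrix has no missing calls).
    """

    groups: list[str]
    n: dict[str, int]
    p: np.ndarray
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(self.groups), len(self.sites)):
            raise ValueError("frequency array shape mismatch")
        if self.p.size and (self.p.min() < 0 or self.p.max() > 1):
            raise ValueError("frequencies must lie in [0, 1]")

    def freq(self, group: str) -> np.ndarray:
        try:
            return self.p[self.groups.index(group)]
        except ValueError:
            raise KeyError(f"unknown group {group!r}") from None


def make_windows(
    chrom_lengths: dict[str, int], size: int = 500_000, step: int = 250_000
) -> pd.DataFrame:
    """Sliding windows (chrom, start, end), 0-based half-open, ordered by
    (chrom, start); the final window is truncated at the chromosome end."""
    if size <= 0 or step <= 0:
        raise ValueError("window size and step must be positive")
    if step > size:
        raise ValueError("step must not exceed window size")
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has nonpositive length")
        start = 0
        while start < length:
            end = min(start + size, length)
            rows.append((chrom, start, end))
            if end == length:  # chromosome covered; no redundant tail windows
                break
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def pool_allele_frequencies(
    matrix: GenotypeMatrix, spec: GroupSpec
) -> PoolFrequencies:
    """Collapse each group's haploid calls into a per-site alt frequency."""
    p = np.empty((len(spec.groups), matrix.n_sites), dtype=float)
    for gi, (group, members) in enumerate(spec.groups.items()):
        idx = matrix.sample_index(members)
        p[gi] = matrix.calls[idx].mean(axis=0) if matrix.n_sites else 0.0
    return PoolFrequencies(
        groups=list(spec.groups),
        n=spec.sizes(),
        p=p,
        sites=matrix.sites,
    )


def site_similarity(p1, p2, method: str = "freq"):
    """Per-site pool similarity in [0, 1]; symmetric. Accepts scalars or
    arrays."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    for p in (p1, p2):
        if p.size and (p.min() < 0 or p.max() > 1):
            raise ValueError("allele frequencies must lie in [0, 1]")
    if method == "freq":
        out = 1.0 - np.abs(p1 - p2)
    elif method == "major":
        m1 = np.where(p1 == 0.5, 0.5, (p1 > 0.5).astype(float))
        m2 = np.where(p2 == 0.5, 0.5, (p2 > 0.5).astype(float))
        agree = (m1 == m2) & (m1 != 0.5)
        tie = (m1 == 0.5) | (m2 == 0.5)
        out = np.where(tie, 0.5, agree.astype(float))
    else:
        raise ValueError(f"unknown similarity method {method!r}")
    return out if out.shape else float(out)


def _window_site_ranges(
    sites: pd.DataFrame, windows: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """For each window, the [i0, i1) slice of the site table it covers."""
    i0 = np.zeros(len(windows), dtype=np.intp)
    i1 = np.zeros(len(windows), dtype=np.intp)
    chrom_arr = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    offsets: dict[str, tuple[int, np.ndarray]] = {}
    for chrom in dict.fromkeys(chrom_arr):
        mask = chrom_arr == chrom
        idx = np.flatnonzero(mask)
        offsets[chrom] = (int(idx[0]), pos[idx])
    for wi, (chrom, start, end) in enumerate(
        windows[["chrom", "start", "end"]].itertuples(index=False)
    ):
        if chrom not in offsets:
            continue
        base, cpos = offsets[chrom]
        i0[wi] = base + np.searchsorted(cpos, start, side="left")
        i1[wi] = base + np.searchsorted(cpos, end, side="left")
    return i0, i1


def window_scan(
    freqs: PoolFrequencies,
    windows: pd.DataFrame,
    focal: str,
    others: Sequence[str],
    method: str = "freq",
) -> pd.DataFrame:
    """Score every window for similarity between the focal pool and each
    other pool.

    Returns a frame with (chrom, start, end, n_snvs, sim_<group>...);
    similarities are NaN for windows with no SNVs.
    """
    if not others:
        raise ValueError("need at least one non-focal group")
    if focal in others:
        raise ValueError("focal group cannot appear among the others")
    pf = freqs.freq(focal)
    i0, i1 = _window_site_ranges(freqs.sites, windows)
    n_snvs = (i1 - i0).astype(int)
    out = windows[["chrom", "start", "end"]].copy()
    out["n_snvs"] = n_snvs
    with np.errstate(invalid="ignore"):
        for g in others:
            s = site_similarity(pf, freqs.freq(g), method=method)
            csum = np.concatenate([[0.0], np.cumsum(s)])
            mean = (csum[i1] - csum[i0]) / np.where(n_snvs > 0, n_snvs, 1)
            out[f"sim_{g}"] = np.where(n_snvs > 0, mean, np.nan)
    return out


def assign_unique_windows(
    records: pd.DataFrame,
    min_snvs: int = 25,
    min_sim: float = 0.95,
) -> pd.DataFrame:
    """Select qualifying windows and assign each to its single most
    similar non-focal group.

    A window qualifies iff n_snvs >= min_snvs and its best similarity is
    >= min_sim.  Exact ties for the best group leave the window
    unassigned (``tie`` flag set) so that assignments stay unique:
    qualifying = assigned + ties, exactly.
    """
    sim_cols = [c for c in records.columns if c.startswith("sim_")]
    groups = [c[len("sim_"):] for c in sim_cols]
    sims = records[sim_cols].to_numpy(dtype=float)
    n_snvs = records["n_snvs"].to_numpy()
    with np.errstate(invalid="ignore"):
        best = np.nanmax(np.where(np.isnan(sims), -np.inf, sims), axis=1)
    qualifying = (n_snvs >= min_snvs) & (best >= min_sim) & np.isfinite(best)
    n_best = (sims == best[:, None]).sum(axis=1)
    tie = qualifying & (n_best > 1)
    arg = np.argmax(np.where(np.isnan(sims), -np.inf, sims), axis=1)

    out = records.copy()
    out["qualifies"] = qualifying
    out["tie"] = tie
    assigned = np.where(
        qualifying & ~tie, np.array(groups, dtype=object)[arg], None
    )
    out["assigned_to"] = assigned
    out["best_sim"] = np.where(qualifying, best, np.nan)
    return out


def summarize_similarity(
    assigned: pd.DataFrame, per_chrom: bool = True
) -> pd.DataFrame:
    """Similarity percentages from total nominal assigned-window length.

    Per chromosome (plus a ``genome`` row), for each non-focal group:
    window count, summed nominal length (end - start, overlaps not
    merged) and percent of the chromosome's total assigned length.
    Chromosomes with no assigned windows are omitted rather than 0/0.
    """
    hits = assigned[assigned["assigned_to"].notna()].copy()
    if hits.empty:
        return pd.DataFrame(
            columns=["chrom", "group", "n_windows", "length", "percent"]
        )
    hits["length"] = hits["end"] - hits["start"]
    scopes = []
    if per_chrom:
        scopes.extend((chrom, sub) for chrom, sub in hits.groupby("chrom", sort=False))
    scopes.append(("genome", hits))
    rows = []
    for scope, sub in scopes:
        total = sub["length"].sum()
        grouped = sub.groupby("assigned_to", sort=False)
        for group, g in grouped:
            length = int(g["length"].sum())
            rows.append(
                (scope, group, len(g), length, 100.0 * length / total)
            )
    return pd.DataFrame(
        rows, columns=["chrom", "group", "n_windows", "length", "percent"]
    )


def export_links(assigned: pd.DataFrame, path: str | Path) -> None:
    """Write assigned windows as a BED-like link table for circos-style
    plotting: chrom, start, end, assigned group, similarity; sorted by
    (chrom, start)."""
    hits = assigned[assigned["assigned_to"].notna()]
    if hits.empty:
        raise ValueError("no assigned windows to export")
    out = hits[["chrom", "start", "end", "assigned_to", "best_sim"]].copy()
    out = out.sort_values(["chrom", "start"], kind="stable")
    out.to_csv(path, sep="\t", index=False, header=False,
               float_format="%.6f")


def read_links(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "assigned_to", "best_sim"],
        dtype={"chrom": str},
    )
    return df
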