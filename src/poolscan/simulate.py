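"""Synthetic four-group genotype panels with planted, recoverable truth.

The generator emulates the study design the pipeline targets: 39 inbred
accessions in four groups (MCB 9, QK 18, Wb-T 6, Wb-NE 6) typed at
biallelic SNVs over multiple chromosomes, fully homozygous with no
missing calls.  Allele frequencies follow the Balding-Nichols model:
an ancestral frequency p ~ Uniform(0.05, 0.95) per site, and each
group's frequency drawn Beta(p(1-F)/F, (1-p)(1-F)/F) with its own
divergence parameter F.  Two kinds of truth blocks are planted:

* shared-ancestry blocks — the focal group and a donor group carry one
  common near-fixed haplotype frequency (drawn with a high block-level
  fixation parameter, as expected for identical-by-descent tracts in
  inbred crop groups), so window similarity between them approaches 1;
* sweep blocks — two named groups are redrawn with a high-divergence
  beta until their frequencies differ by at least a floor (a floor of
  1 plants exact fixed differences), so windowed FST spikes.

Each accession then draws a single allele per site (Bernoulli with its
group's frequency), written as a homozygous diploid call.  Gene
annotations (uniform non-overlapping intervals) and AT-rich chromosome
sequences with planted CG-rich islands complete the inputs every
pipeline stage needs.  Everything is deterministic under the config
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .snv_matrix import SITE_COLUMNS, GenotypeMatrix, GroupSpec

__all__ = [
    "SharedBlock",
    "SweepBlock",
    "SimConfig",
    "TruthSet",
    "default_config",
    "simulate_frequencies",
    "simulate_genotypes",
    "write_vcf",
    "write_group_tsv",
    "simulate_annotation_and_sequence",
    "write_fasta",
    "evaluate_recovery",
]


@dataclass
class SharedBlock:
    """Focal group copies the donor group's (near-fixed) frequencies."""

    chrom: str
    start: int
    end: int
    donor: str


@dataclass
class SweepBlock:
    """Two groups forced apart by at least ``min_delta`` in frequency."""

    chrom: str
    start: int
    end: int
    group1: str
    group2: str
    min_delta: float = 0.8


@dataclass
class SimConfig:
    chrom_lengths: dict[str, int]
    n_sites: dict[str, int]
    group_sizes: dict[str, int]
    divergence: dict[str, float]
    focal_group: str = "MCB"
    shared_blocks: list[SharedBlock] = field(default_factory=list)
    sweep_blocks: list[SweepBlock] = field(default_factory=list)
    shared_fixation: float = 0.98
    sweep_divergence: float = 0.8
    n_genes: int = 60
    gene_length: int = 3000
    seq_length: int = 300_000
    n_islands: int = 3
    island_length: int = 12_000
    seed: int = 42

    def __post_init__(self) -> None:
        for g, f in self.divergence.items():
            if not 0 < f < 1:
                raise ValueError(f"divergence F for {g!r} must lie in (0, 1)")
        for blocks in (self.shared_blocks, self.sweep_blocks):
            spans: dict[str, list[tuple[int, int]]] = {}
            for b in blocks:
                if b.chrom not in self.chrom_lengths:
                    raise ValueError(f"block on unknown chromosome {b.chrom!r}")
                if not 0 <= b.start < b.end <= self.chrom_lengths[b.chrom]:
                    raise ValueError(f"block [{b.start}, {b.end}) out of bounds")
                for s, e in spans.get(b.chrom, []):
                    if b.start < e and s < b.end:
                        raise ValueError("planted blocks overlap")
                spans.setdefault(b.chrom, []).append((b.start, b.end))

    def group_spec(self) -> GroupSpec:
        return GroupSpec(
            {
                g: [f"{g}_{i + 1:02d}" for i in range(n)]
                for g, n in self.group_sizes.items()
            }
        )


@dataclass
class TruthSet:
    """Ground truth of one simulation: planted blocks, generating
    frequencies and site coordinates; serialisable to JSON (frequencies
    to a sidecar TSV)."""

    config: SimConfig
    sites: pd.DataFrame  # chrom, pos (0-based), ref, alt
    frequencies: np.ndarray  # n_groups x n_sites, group order of config
    groups: list[str]

    def block_sites(self, chrom: str, start: int, end: int) -> np.ndarray:
        m = (
            (self.sites["chrom"] == chrom)
            & (self.sites["pos"] >= start)
            & (self.sites["pos"] < end)
        )
        return np.flatnonzero(m.to_numpy())

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = {
            "config": asdict(self.config),
            "groups": self.groups,
            "frequencies_tsv": path.name + ".freq.tsv",
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        out = self.sites.copy()
        for gi, g in enumerate(self.groups):
            out[g] = self.frequencies[gi]
        out.to_csv(str(path) + ".freq.tsv", sep="\t", index=False,
                   float_format="%.8f")

    @classmethod
    def load(cls, path: str | Path) -> "TruthSet":
        path = Path(path)
        payload = json.loads(path.read_text())
        cfg = payload["config"]
        cfg["shared_blocks"] = [SharedBlock(**b) for b in cfg["shared_blocks"]]
        cfg["sweep_blocks"] = [SweepBlock(**b) for b in cfg["sweep_blocks"]]
        config = SimConfig(**cfg)
        df = pd.read_csv(str(path) + ".freq.tsv", sep="\t", dtype={"chrom": str})
        groups = payload["groups"]
        sites = df[list(SITE_COLUMNS)].copy()
        freqs = df[groups].to_numpy().T
        return cls(config=config, sites=sites, frequencies=freqs, groups=groups)


def default_config(seed: int = 42) -> SimConfig:
    """The demo study design: 2 x 50-Mb chromosomes, 25k SNVs each,
    groups MCB 9 / QK 18 / Wb-T 6 / Wb-NE 6, six 2-Mb shared blocks
    (donors QK and Wb-T) and four 1-Mb QK-vs-MCB sweep blocks."""
    L = 50_000_000
    return SimConfig(
        chrom_lengths={"1H": L, "2H": L},
        n_sites={"1H": 25_000, "2H": 25_000},
        group_sizes={"MCB": 9, "QK": 18, "Wb-T": 6, "Wb-NE": 6},
        divergence={"MCB": 0.15, "QK": 0.15, "Wb-T": 0.2, "Wb-NE": 0.3},
        focal_group="MCB",
        shared_blocks=[
            SharedBlock("1H", 5_000_000, 7_000_000, "QK"),
            SharedBlock("1H", 15_000_000, 17_000_000, "QK"),
            SharedBlock("1H", 30_000_000, 32_000_000, "Wb-T"),
            SharedBlock("2H", 8_000_000, 10_000_000, "QK"),
            SharedBlock("2H", 20_000_000, 22_000_000, "Wb-T"),
            SharedBlock("2H", 40_000_000, 42_000_000, "QK"),
        ],
        sweep_blocks=[
            SweepBlock("1H", 22_000_000, 23_000_000, "QK", "MCB"),
            SweepBlock("1H", 40_000_000, 41_000_000, "QK", "MCB"),
            SweepBlock("2H", 5_000_000, 6_000_000, "QK", "MCB"),
            SweepBlock("2H", 30_000_000, 31_000_000, "QK", "MCB"),
        ],
        seed=seed,
    )


def _beta_bn(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Balding-Nichols draw: Beta(p(1-F)/F, (1-p)(1-F)/F) around p."""
    scale = (1 - f) / f
    return rng.beta(np.maximum(p * scale, 1e-9),
                    np.maximum((1 - p) * scale, 1e-9))


_MAX_SWEEP_TRIES = 1000


def simulate_frequencies(config: SimConfig) -> TruthSet:
    """Draw per-group per-site allele frequencies with planted blocks."""
    rng = np.random.default_rng(config.seed)
    groups = list(config.group_sizes)
    site_rows = []
    freq_cols = []
    bases = np.array(list("ACGT"))
    for chrom, length in config.chrom_lengths.items():
        n = config.n_sites[chrom]
        pos = np.sort(rng.choice(length, size=n, replace=False))
        anc = rng.uniform(0.05, 0.95, size=n)
        freqs = np.stack(
            [_beta_bn(rng, anc, config.divergence[g]) for g in groups]
        )
        for block in config.shared_blocks:
            if block.chrom != chrom:
                continue
            m = (pos >= block.start) & (pos < block.end)
            shared = _beta_bn(rng, anc[m], config.shared_fixation)
            freqs[groups.index(config.focal_group), m] = shared
            freqs[groups.index(block.donor), m] = shared
        for block in config.sweep_blocks:
            if block.chrom != chrom:
                continue
            m = np.flatnonzero((pos >= block.start) & (pos < block.end))
            i1, i2 = groups.index(block.group1), groups.index(block.group2)
            if block.min_delta >= 0.999:
                flip = rng.random(m.size) < 0.5
                freqs[i1, m] = flip.astype(float)
                freqs[i2, m] = 1.0 - flip
                continue
            for s in m:
                for attempt in range(_MAX_SWEEP_TRIES):
                    q1 = _beta_bn(rng, anc[s : s + 1], config.sweep_divergence)[0]
                    q2 = _beta_bn(rng, anc[s : s + 1], config.sweep_divergence)[0]
                    if abs(q1 - q2) >= block.min_delta:
                        freqs[i1, s] = q1
                        freqs[i2, s] = q2
                        break
                else:
                    raise RuntimeError(
                        f"could not satisfy |dp| >= {block.min_delta} at "
                        f"{chrom}:{pos[s]} after {_MAX_SWEEP_TRIES} tries; "
                        "lower the floor or raise sweep_divergence"
                    )
        ref = bases[rng.integers(0, 4, size=n)]
        alt_shift = rng.integers(1, 4, size=n)
        alt = bases[(np.searchsorted(bases, ref) + alt_shift) % 4]
        site_rows.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt}
            )
        )
        freq_cols.append(freqs)
    sites = pd.concat(site_rows, ignore_index=True)
    frequencies = np.concatenate(freq_cols, axis=1)
    return TruthSet(config=config, sites=sites, frequencies=frequencies,
                    groups=groups)


def simulate_genotypes(
    truth: TruthSet, seed: Optional[int] = None
) -> GenotypeMatrix:
    """One haploid allele per accession per site, Bernoulli with its
    group's frequency.  ``seed`` defaults to config.seed + 1 so the
    frequency and genotype streams are independent but reproducible."""
    config = truth.config
    if seed is None:
        seed = config.seed + 1
    rng = np.random.default_rng(seed)
    spec = config.group_spec()
    n_sites = len(truth.sites)
    calls = np.empty((len(spec.samples), n_sites), dtype=np.uint8)
    row = 0
    for gi, (g, members) in enumerate(spec.groups.items()):
        p = truth.frequencies[truth.groups.index(g)]
        for _ in members:
            calls[row] = rng.random(n_sites) < p
            row += 1
    return GenotypeMatrix(samples=spec.samples, sites=truth.sites.copy(),
                          calls=calls)


def write_vcf(
    matrix: GenotypeMatrix,
    path: str | Path,
    chrom_lengths: Optional[dict[str, int]] = None,
    mq: int = 60,
    depth: int = 20,
) -> None:
    """Serialise the matrix as a homozygous-diploid VCF with site MQ and
    per-sample DP fields that pass the default ingestion filters."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=poolscan-simulate\n")
        if chrom_lengths:
            for chrom, length in chrom_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        else:
            for chrom in matrix.chroms:
                sub = matrix.sites[matrix.sites["chrom"] == chrom]
                fh.write(
                    f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 2}>\n"
                )
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        gt_strings = np.array([f"0/0:{depth}", f"1/1:{depth}"])
        for j, (chrom, pos, ref, alt) in enumerate(
            matrix.sites[list(SITE_COLUMNS)].itertuples(index=False)
        ):
            cells = gt_strings[matrix.calls[:, j]]
            fh.write(
                f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\tMQ={mq}\t"
                "GT:DP\t" + "\t".join(cells) + "\n"
            )


def write_group_tsv(spec: GroupSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        for group, members in spec.groups.items():
            for s in members:
                fh.write(f"{s}\t{group}\n")


def simulate_annotation_and_sequence(
    config: SimConfig, seed: Optional[int] = None
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Gene intervals, AT-rich sequences with planted CpG islands, and
    the island truth table.

    Genes: ``n_genes`` non-overlapping uniform intervals of
    ``gene_length`` bp across the chromosomes (full genotype coordinate
    system).  Sequences: per chromosome, ``seq_length`` bp of AT-rich
    background (GC ~ 0.35, CpG obs/exp ~ 1 but GC below threshold) with
    ``n_islands`` planted CG-rich segments (GC ~ 0.8).  Returns
    (genes, {chrom: seq}, island truth with chrom/start/end).
    """
    if seed is None:
        seed = config.seed + 2
    rng = np.random.default_rng(seed)

    chroms = list(config.chrom_lengths)
    gene_rows = []
    per_chrom = np.array_split(np.arange(config.n_genes), len(chroms))
    for chrom, idx in zip(chroms, per_chrom):
        length = config.chrom_lengths[chrom]
        k = len(idx)
        if k == 0:
            continue
        slot = length // k
        if slot <= config.gene_length:
            raise ValueError(
                f"cannot place {k} non-overlapping {config.gene_length}-bp "
                f"genes on {chrom} ({length} bp)"
            )
        offsets = rng.integers(0, slot - config.gene_length, size=k)
        starts = np.arange(k) * slot + offsets
        for gi, s in zip(idx, starts):
            gene_rows.append(
                (chrom, int(s), int(s) + config.gene_length, f"gene_{gi + 1:04d}")
            )
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "gene_id"])

    background = np.array(list("ATCG"))
    bg_p = np.array([0.325, 0.325, 0.175, 0.175])  # GC ~ 0.35
    island_p = np.array([0.10, 0.10, 0.40, 0.40])  # GC ~ 0.80
    seqs: dict[str, str] = {}
    island_rows = []
    for chrom in chroms:
        n = config.seq_length
        arr = rng.choice(background, size=n, p=bg_p)
        k = config.n_islands
        if k:
            slot = n // k
            if slot <= config.island_length:
                raise ValueError("islands do not fit without overlap")
            offsets = rng.integers(0, slot - config.island_length, size=k)
            for i in range(k):
                s = int(i * slot + offsets[i])
                e = s + config.island_length
                arr[s:e] = rng.choice(background, size=e - s, p=island_p)
                island_rows.append((chrom, s, e))
        seqs[chrom] = "".join(arr)
    islands = pd.DataFrame(island_rows, columns=["chrom", "start", "end"])
    return genes, seqs, islands


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gene_bed(genes: pd.DataFrame, path: str | Path) -> None:
    genes[["chrom", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def evaluate_recovery(
    truth: TruthSet,
    assigned_windows: Optional[pd.DataFrame] = None,
    sweep_regions: Optional[pd.DataFrame] = None,
    fst_windows: Optional[pd.DataFrame] = None,
) -> dict[str, float]:
    """Score pipeline outputs against the planted truth.

    * ``shared_block_accuracy``: fraction of planted shared blocks whose
      overlapping assigned windows majority-vote the true donor;
    * ``sweep_sensitivity``: fraction of planted sweep blocks overlapped
      by at least one called region;
    * ``sweep_false_positive_rate``: fraction of truly-neutral windows
      (no sweep-block overlap) with fst above threshold, computed from
      the called regions' member windows.

    Metrics whose inputs are absent (or whose truth list is empty) are
    left out of the result rather than reported as NaN.
    """
    metrics: dict[str, float] = {}
    cfg = truth.config

    if assigned_windows is not None and cfg.shared_blocks:
        correct = 0
        for block in cfg.shared_blocks:
            sub = assigned_windows[
                (assigned_windows["chrom"] == block.chrom)
                & (assigned_windows["start"] < block.end)
                & (assigned_windows["end"] > block.start)
                & assigned_windows["assigned_to"].notna()
            ]
            if len(sub) == 0:
                continue
            votes = sub["assigned_to"].value_counts()
            if votes.idxmax() == block.donor and votes.max() * 2 > len(sub):
                correct += 1
        metrics["shared_block_accuracy"] = correct / len(cfg.shared_blocks)

    if sweep_regions is not None and cfg.sweep_blocks:
        hit = 0
        for block in cfg.sweep_blocks:
            sub = sweep_regions[
                (sweep_regions["chrom"] == block.chrom)
                & (sweep_regions["start"] < block.end)
                & (sweep_regions["end"] > block.start)
            ]
            if len(sub):
                hit += 1
        metrics["sweep_sensitivity"] = hit / len(cfg.sweep_blocks)

    if fst_windows is not None and sweep_regions is not None and cfg.sweep_blocks:
        in_sweep = np.zeros(len(fst_windows), dtype=bool)
        called = np.zeros(len(fst_windows), dtype=bool)
        for i, (chrom, s, e) in enumerate(
            fst_windows[["chrom", "start", "end"]].itertuples(index=False)
        ):
            for block in cfg.sweep_blocks:
                if block.chrom == chrom and s < block.end and block.start < e:
                    in_sweep[i] = True
                    break
            sub = sweep_regions[
                (sweep_regions["chrom"] == chrom)
                & (sweep_regions["start"] < e)
                & (sweep_regions["end"] > s)
            ]
            # a window is "called" when fully inside a merged region
            for rs, re in sub[["start", "end"]].itertuples(index=False):
                if rs <= s and e <= re:
                    called[i] = True
                    break
        neutral = ~in_sweep
        if neutral.any():
            metrics["sweep_false_positive_rate"] = float(
                (called & neutral).sum() / neutral.sum()
            )
    return metrics
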