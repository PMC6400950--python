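"""Synthetic replicate generator emulating a spike-in dilution benchmark.

Generates per-replicate pileups over a synthetic contig with the three
evidence layers the joint model distinguishes:

* true variants — shared positions/alleles across replicates, per-replicate
  read counts Binomial(n, VAF) at the configured spike-in VAFs
  (0.5/1/5/10% by default, mirroring dilution ratios 0.01/0.02/0.1/0.2);
* background errors — library-preparation artifacts drawn independently per
  library replicate: a site acquires one with probability f_BE, its error
  VAF is Exp(lambda) for the site's substitution type (truncated to (0, 1]),
  and reads follow Binomial(n, x_err) with *high* base qualities, which is
  what makes these errors invisible to quality-based filtering;
* sequencing errors — every read flips to a random alt with probability
  10^(-q/10) under the configured base-quality mixture.

``sequencing_replicate`` resamples only the sequencing layer while sharing
the library's background-error sites and their molecule fractions,
reproducing pseudo-replicate (re-sequencing) semantics: background errors
recur concordantly and cannot be exposed by such replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .pileup_io import (
    BASES,
    PileupSeries,
    ReplicateSet,
    SiteObservation,
    TargetRegion,
    normalize_substitution,
)

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "spectrum_preset",
    "simulate_replicates",
    "sequencing_replicate",
]

#: Post-filter Illumina-like binned base-quality mixture (fractions of reads
#: at each Phred bin after the default min-BQ-20 pileup filter).
DEFAULT_BASE_QUALITY_WEIGHTS = {41: 0.46, 37: 0.36, 32: 0.10, 27: 0.05, 22: 0.03}

#: Per-substitution exponential rates (1/VAF). Absolute magnitudes are
#: artifact choices; the orderings encode the published platform signatures:
#: amplicon/PCR libraries show excess A>G (T>C) and C>T (G>A) transitions
#: (PCR error), hybrid capture shows excess C>A (G>T) from oxidative damage
#: during sonication. Smaller lambda = heavier errors.
SPECTRUM_PRESETS: dict[str, tuple[dict[str, float], float]] = {
    "amplicon_pcr": (
        {"A>C": 600.0, "A>G": 150.0, "A>T": 700.0,
         "C>A": 450.0, "C>G": 800.0, "C>T": 150.0},
        0.01,
    ),
    "capture": (
        {"A>C": 700.0, "A>G": 550.0, "A>T": 750.0,
         "C>A": 200.0, "C>G": 800.0, "C>T": 500.0},
        0.003,
    ),
}


def spectrum_preset(name: str) -> tuple[dict[str, float], float]:
    """(lambda_by_type, f_BE) for a named platform error signature."""
    try:
        lambdas, f_be = SPECTRUM_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(SPECTRUM_PRESETS)}"
        ) from None
    return dict(lambdas), f_be


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic replicate experiment."""

    seed: int
    target_bp: int = 100_000
    depth: int = 1000
    k: int = 2
    true_vafs: Sequence[float] = (0.005, 0.01, 0.05, 0.10)
    n_true_sites: int = 100
    lambda_by_type: dict[str, float] = field(
        default_factory=lambda: dict(SPECTRUM_PRESETS["amplicon_pcr"][0])
    )
    f_be: float = 0.01
    base_quality_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_QUALITY_WEIGHTS)
    )
    with_control: bool = True
    contig: str = "sim1"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        if self.target_bp <= 0 or self.depth <= 0 or self.k < 1:
            raise ValueError("target_bp, depth and k must be positive")
        if not 0.0 <= self.f_be < 1.0:
            raise ValueError("f_be must lie in [0, 1)")
        if self.n_true_sites > self.target_bp:
            raise ValueError("more true sites than target positions")
        if any(not 0.0 < v <= 1.0 for v in self.true_vafs):
            raise ValueError("true VAFs must lie in (0, 1]")
        if any(lam <= 0 for lam in self.lambda_by_type.values()):
            raise ValueError("error rates lambda must be positive")

    def region(self) -> TargetRegion:
        return TargetRegion(self.contig, 0, self.target_bp)


@dataclass
class TruthSet:
    """Simulator ground truth: spiked-in variants with their true VAFs."""

    records: list[tuple[str, int, str, str, float]]  # chrom, pos, ref, alt, vaf
    target_bp: int

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {(c, p, r, a) for c, p, r, a, _ in self.records}

    def keys_at_vaf(self, vaf: float) -> set[tuple[str, int, str, str]]:
        return {(c, p, r, a) for c, p, r, a, v in self.records if v == vaf}

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\ttrue_vaf\n")
            for chrom, pos, ref, alt, vaf in sorted(self.records):
                fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{vaf:g}\n")

    @classmethod
    def read_tsv(cls, path: str, target_bp: int = 0) -> "TruthSet":
        records = []
        with open(path) as fh:
            fh.readline()
            for line in fh:
                if not line.strip():
                    continue
                chrom, pos, ref, alt, vaf = line.rstrip("\n").split("\t")
                records.append((chrom, int(pos), ref, alt, float(vaf)))
        return cls(records, target_bp)


class _QualitySampler:
    """Draws Phred base qualities from the configured mixture; error reads
    use the error-posterior weights w_q * 10^(-q/10)."""

    def __init__(self, weights: dict[int, float]) -> None:
        if not weights or any(w < 0 for w in weights.values()):
            raise ValueError("base-quality weights must be non-negative")
        qs = sorted(weights)
        w = np.array([weights[q] for q in qs], dtype=float)
        w = w / w.sum()
        self.values = np.array(qs)
        self.cum = np.cumsum(w)
        err_w = w * np.power(10.0, -self.values / 10.0)
        self.p_error = float(err_w.sum())
        self.err_cum = np.cumsum(err_w / err_w.sum())

    def draw(self, rng: np.random.Generator, n: int, error_reads: bool = False):
        cum = self.err_cum if error_reads else self.cum
        idx = np.searchsorted(cum, rng.random(n))
        return [int(v) for v in self.values[idx]]


@dataclass
class ReplicateLayers:
    """Generative decomposition of one replicate, retained so the
    sequencing layer can be resampled independently of the library."""

    config: SimulationConfig
    ref_idx: np.ndarray
    bg: dict[int, tuple[str, float]]      # 0-based pos -> (alt, x_err)
    truth: dict[int, tuple[str, float]]   # 0-based pos -> (alt, true VAF)


def _truncated_exponential(rng: np.random.Generator, scale: float) -> float:
    x = rng.exponential(scale)
    while x > 1.0:  # renormalizing truncation; negligible mass for real rates
        x = rng.exponential(scale)
    return float(x)


def _other_bases(ref: str) -> list[str]:
    return [b for b in BASES if b != ref]


def _assemble_replicate(
    config: SimulationConfig,
    ref_idx: np.ndarray,
    layers: ReplicateLayers,
    rng: np.random.Generator,
    sampler: _QualitySampler,
    name: str,
) -> PileupSeries:
    """Draw the read-level observation of one replicate given its library
    layers: sequencing errors, Binomial(n, x_err) background reads and
    Binomial(n, VAF) variant reads, with base qualities per layer."""
    depth = config.depth
    seq_counts = rng.binomial(depth, sampler.p_error, size=config.target_bp)
    bg_reads = {
        pos: (alt, int(rng.binomial(depth, x))) for pos, (alt, x) in sorted(layers.bg.items())
    }
    true_reads = {
        pos: (alt, int(rng.binomial(depth, vaf)))
        for pos, (alt, vaf) in sorted(layers.truth.items())
    }
    positions = sorted(
        set(np.nonzero(seq_counts)[0].tolist())
        | {p for p, (_, b) in bg_reads.items() if b > 0}
        | {p for p, (_, b) in true_reads.items() if b > 0}
    )
    series = PileupSeries(
        regions=[config.region()], uniform_depth=depth, name=name
    )
    for pos in positions:
        ref = BASES[ref_idx[pos]]
        counts: dict[str, int] = {}
        quals: dict[str, list[int]] = {}
        n_seq = int(seq_counts[pos])
        if n_seq:
            split = rng.multinomial(n_seq, [1 / 3] * 3)
            for base, c in zip(_other_bases(ref), split):
                if c:
                    counts[base] = counts.get(base, 0) + int(c)
                    quals.setdefault(base, []).extend(
                        sampler.draw(rng, int(c), error_reads=True)
                    )
        for source in (bg_reads, true_reads):
            if pos in source:
                alt, b = source[pos]
                if b:
                    counts[alt] = counts.get(alt, 0) + b
                    quals.setdefault(alt, []).extend(sampler.draw(rng, b))
        # cap pathological layer overlaps at the site depth
        while sum(counts.values()) > depth:
            top = max(counts, key=lambda a: (counts[a], a))
            counts[top] -= 1
            quals[top].pop()
            if counts[top] == 0:
                del counts[top], quals[top]
        if counts:
            series.add(
                SiteObservation(
                    config.contig, pos + 1, ref, depth, counts,
                    {a: quals[a] for a in counts},
                )
            )
    series.layers = layers  # type: ignore[attr-defined]
    return series


def _draw_background_layer(
    config: SimulationConfig, ref_idx: np.ndarray, rng: np.random.Generator
) -> dict[int, tuple[str, float]]:
    bg: dict[int, tuple[str, float]] = {}
    if config.f_be <= 0:
        return bg
    hit = np.nonzero(rng.random(config.target_bp) < config.f_be)[0]
    for pos in hit.tolist():
        ref = BASES[ref_idx[pos]]
        alt = _other_bases(ref)[rng.integers(0, 3)]
        lam = config.lambda_by_type[normalize_substitution(ref, alt)]
        bg[pos] = (alt, _truncated_exponential(rng, 1.0 / lam))
    return bg


def simulate_replicates(
    config: SimulationConfig,
) -> tuple[ReplicateSet, TruthSet]:
    """Generate k library replicates (plus a matched, variant-free control
    when configured) and the ground-truth spike-in set.

    True variants are shared across replicates (same positions, alleles and
    molecule fractions); background errors are drawn independently per
    library replicate — the premise that makes library-level replication
    informative. Deterministic for a given config (the seed fans out to one
    independent stream per replicate).
    """
    root = np.random.SeedSequence(config.seed)
    n_streams = 1 + config.k + 1
    streams = [np.random.default_rng(s) for s in root.spawn(n_streams)]
    genome_rng, rep_rngs, control_rng = streams[0], streams[1:-1], streams[-1]
    sampler = _QualitySampler(config.base_quality_weights)

    ref_idx = genome_rng.integers(0, 4, size=config.target_bp)
    truth_records: list[tuple[str, int, str, str, float]] = []
    truth_layer: dict[int, tuple[str, float]] = {}
    if config.n_true_sites:
        positions = np.sort(
            genome_rng.choice(config.target_bp, size=config.n_true_sites, replace=False)
        )
        for i, pos in enumerate(positions.tolist()):
            ref = BASES[ref_idx[pos]]
            alt = _other_bases(ref)[genome_rng.integers(0, 3)]
            vaf = config.true_vafs[i % len(config.true_vafs)]
            truth_layer[pos] = (alt, vaf)
            truth_records.append((config.contig, pos + 1, ref, alt, vaf))

    replicates = []
    for j, rng in enumerate(rep_rngs, start=1):
        layers = ReplicateLayers(
            config=config,
            ref_idx=ref_idx,
            bg=_draw_background_layer(config, ref_idx, rng),
            truth=dict(truth_layer),
        )
        replicates.append(
            _assemble_replicate(config, ref_idx, layers, rng, sampler, f"rep{j}")
        )

    control = None
    if config.with_control:
        layers = ReplicateLayers(
            config=config,
            ref_idx=ref_idx,
            bg=_draw_background_layer(config, ref_idx, control_rng),
            truth={},
        )
        control = _assemble_replicate(
            config, ref_idx, layers, control_rng, sampler, "control"
        )

    reps = ReplicateSet(
        replicates=replicates, control=control, regions=[config.region()]
    )
    return reps, TruthSet(truth_records, config.target_bp)


def sequencing_replicate(rep: PileupSeries, seed: int) -> PileupSeries:
    """Re-sequence the same library: only the sequencing-error layer and the
    read sampling are redrawn; background-error sites and their molecule
    fractions x_err are shared with the source replicate, so they recur at
    identical positions with concordant expected VAFs."""
    layers: ReplicateLayers = getattr(rep, "layers", None)
    if layers is None:
        raise ValueError(
            "source replicate lacks simulation layers; only simulated "
            "replicates can be re-sequenced"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sampler = _QualitySampler(layers.config.base_quality_weights)
    return _assemble_replicate(
        layers.config, layers.ref_idx, layers, rng, sampler,
        name=f"{rep.name}-reseq",
    )
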