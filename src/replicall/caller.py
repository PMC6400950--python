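"""Joint replicate scoring and candidate calling.

Every candidate site i (any alt allele with at least one supporting read in
at least one replicate) is scored across k replicates with the log-odds of a
variant model M_v against the background-error model M_0:

    S = log( phi_v * prod_j N(x_BE_j; mu_hat, sigma_hat_j^2) )
      - log( phi_BE * prod_j Exp(x_BE_j; lambda_BE) )

where mu_hat is the mean adjusted VAF over replicates, the per-replicate
sigma_hat_j = sqrt(mu_hat (1 - mu_hat) / n_j) comes from the normal
approximation to the binomial, and lambda_BE is the fitted exponential rate
for the site's substitution type. All replicates sharing a true variant show
concordant adjusted VAFs, so the Gaussian product rewards concordance while
the prior is applied once regardless of k. Sites with S > 0 are variant
candidates; configurable post-filters then flag (never delete) calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .error_model import (
    ErrorProfile,
    Priors,
    adjust_observation,
    compute_priors,
    fit_error_profile,
    build_germline_mask,
    log_error_likelihood,
)
from .pileup_io import (
    PileupSeries,
    ReplicateSet,
    SiteObservation,
    TargetRegion,
    normalize_substitution,
)

__all__ = [
    "CallerConfig",
    "ReplicateEvidence",
    "CallRecord",
    "mean_adjusted_vaf",
    "variant_likelihood",
    "log_variant_likelihood",
    "score_site",
    "call_variants",
    "apply_postfilters",
    "run_pipeline",
    "write_audit_table",
]

#: Densities are floored before logging so a single extreme replicate cannot
#: produce an infinite score.
DENSITY_FLOOR = 1e-300
LOG_FLOOR = math.log(DENSITY_FLOOR)

#: mu_hat is clamped away from the degenerate {0, 1} endpoints.
MU_EPS = 1e-6

LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class CallerConfig:
    """Tunable calling parameters.

    f_v is the prior somatic mutation frequency — the only model parameter a
    user must think about (default 3e-6, a typical somatic rate). The
    remaining fields configure post-filters; ``mode='amplicon'`` disables the
    strand-bias filter, which amplicon libraries violate by design.
    """

    f_v: float = 3e-6
    min_alt_reads_per_rep: int = 2
    min_depth: int = 100
    mode: str = "capture"  # "capture" | "amplicon"
    strand_bias_p: float = 0.005
    triallelic_vaf_ratio: float = 0.5
    blacklist: Sequence[TargetRegion] = ()
    blacklist_pad: int = 5

    def __post_init__(self) -> None:
        if self.f_v <= 0:
            raise ValueError("f_v must be positive")
        if self.min_alt_reads_per_rep < 0 or self.min_depth < 0:
            raise ValueError("thresholds must be non-negative")
        if self.mode not in ("capture", "amplicon"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class ReplicateEvidence:
    """Per-replicate raw and adjusted evidence for one scored allele."""

    n: int
    b: int
    x: float
    b_se: float
    b_be: float
    x_be: float       # clamped to >= 0 for scoring
    sigma_hat: float


@dataclass
class CallRecord:
    """A scored candidate site with all intermediates and filter flags."""

    chrom: str
    pos: int
    ref: str
    alt: str
    substitution: str
    evidence: list[ReplicateEvidence]
    mu_hat: float
    lambda_be: float
    s: float
    filters: list[str] = field(default_factory=list)

    @property
    def called(self) -> bool:
        """Strictly positive score and no failed post-filters."""
        return self.s > 0 and not self.filters

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def mean_adjusted_vaf(x_be_values: Sequence[float]) -> float:
    """mu_hat: arithmetic mean of the per-replicate adjusted VAFs."""
    if len(x_be_values) == 0:
        raise ValueError("need at least one replicate")
    return float(sum(x_be_values) / len(x_be_values))


def variant_likelihood(x_be: float, n: int, mu_hat: float) -> float:
    """M_v density: normal with mean mu_hat and variance mu_hat(1-mu_hat)/n
    (binomial normal approximation on the VAF scale)."""
    return math.exp(log_variant_likelihood(x_be, n, mu_hat))


def log_variant_likelihood(x_be: float, n: int, mu_hat: float) -> float:
    if n <= 0:
        raise ValueError("depth must be positive")
    if not 0.0 < mu_hat < 1.0:
        raise ValueError("mu_hat must lie strictly between 0 and 1")
    var = mu_hat * (1.0 - mu_hat) / n
    return -0.5 * (LOG_2PI + math.log(var)) - (x_be - mu_hat) ** 2 / (2.0 * var)


def score_site(
    observations: Sequence[SiteObservation],
    alt: str,
    profile: ErrorProfile,
    priors: Priors,
) -> Optional[CallRecord]:
    """Score one (position, alt allele) jointly across replicates.

    Zero-coverage replicates contribute no evidence either way and are
    dropped (k shrinks for that site). Returns ``None`` for sites the model
    cannot score: no covered replicate, or no replicate with b_BE > 0.
    """
    covered = [obs for obs in observations if obs.depth > 0]
    if not covered:
        return None
    ref = next((o.ref for o in covered if o.ref != "N"), None)
    if ref is None:
        return None

    adjusted = [adjust_observation(obs, alt) for obs in covered]
    if not any(a.b_be > 0 for a in adjusted):
        return None  # pure sequencing-error site under the model

    substitution = normalize_substitution(ref, alt)
    lam = profile.lambda_for(substitution)

    x_be = [max(a.x_be, 0.0) for a in adjusted]
    mu_hat = mean_adjusted_vaf(x_be)
    if mu_hat <= 0.0:
        return None
    mu_hat = min(max(mu_hat, MU_EPS), 1.0 - MU_EPS)

    log_num = max(math.log(priors.phi_v) if priors.phi_v > 0 else -math.inf, LOG_FLOOR)
    log_den = max(math.log(priors.phi_be) if priors.phi_be > 0 else -math.inf, LOG_FLOOR)
    evidence = []
    for obs, adj, x in zip(covered, adjusted, x_be):
        sigma = math.sqrt(mu_hat * (1.0 - mu_hat) / obs.depth)
        log_num += max(log_variant_likelihood(x, obs.depth, mu_hat), LOG_FLOOR)
        log_den += max(log_error_likelihood(x, lam), LOG_FLOOR)
        evidence.append(
            ReplicateEvidence(
                n=obs.depth,
                b=adj.b,
                x=obs.vaf(alt),
                b_se=adj.b_se,
                b_be=adj.b_be,
                x_be=x,
                sigma_hat=sigma,
            )
        )
    return CallRecord(
        chrom=covered[0].chrom,
        pos=covered[0].pos,
        ref=ref,
        alt=alt,
        substitution=substitution,
        evidence=evidence,
        mu_hat=mu_hat,
        lambda_be=lam,
        s=log_num - log_den,
    )


def call_variants(
    reps: ReplicateSet,
    profile: ErrorProfile,
    config: CallerConfig,
    priors: Optional[Priors] = None,
    germline_mask: frozenset | set = frozenset(),
) -> list[CallRecord]:
    """Score every candidate (position x alt allele) and return the scored
    records in deterministic (chrom, pos, alt) order.

    Each alt allele is scored independently against the same reference, so a
    triallelic site yields one record per allele (error accumulation at high
    depth makes such sites common false-negative traps). All scored records
    are returned — including S <= 0 rejections — for auditability; callers
    select on ``record.s > 0``.
    """
    if priors is None:
        priors = compute_priors(config.f_v, profile.f_be)
    records: list[CallRecord] = []
    for key in reps.candidate_positions():
        if key in germline_mask:
            continue
        chrom, pos = key
        observations = [rep.get(chrom, pos) for rep in reps.replicates]
        alleles = sorted({a for obs in observations for a in obs.alt_counts})
        for alt in alleles:
            record = score_site(observations, alt, profile, priors)
            if record is not None:
                records.append(record)
    records.sort(key=lambda r: (r.chrom, r.pos, r.alt))
    return records


# ---------------------------------------------------------------------------
# Post-filters
# ---------------------------------------------------------------------------

def _strand_bias_flagged(
    reps: ReplicateSet, record: CallRecord, p_threshold: float
) -> bool:
    """Fisher exact test of alt vs ref reads across strands, per replicate;
    the site is flagged only when biased (p below threshold) in every
    replicate that carries strand information."""
    from scipy.stats import fisher_exact

    tested = 0
    for rep in reps.replicates:
        obs = rep.get(record.chrom, record.pos)
        if obs.depth == 0:
            continue
        if obs.alt_fwd is None or obs.ref_fwd is None:
            return False  # no strand info available; cannot assess
        b = obs.alt_counts.get(record.alt, 0)
        if b == 0:
            continue
        alt_fwd = obs.alt_fwd.get(record.alt, 0)
        ref_total = obs.depth - sum(obs.alt_counts.values())
        table = [
            [alt_fwd, b - alt_fwd],
            [obs.ref_fwd, ref_total - obs.ref_fwd],
        ]
        _, p = fisher_exact(table)
        if p >= p_threshold:
            return False
        tested += 1
    return tested > 0


def apply_postfilters(
    calls: list[CallRecord],
    reps: ReplicateSet,
    config: CallerConfig,
) -> list[CallRecord]:
    """Flag systematic errors the probabilistic model cannot capture.

    Filters flag rather than remove; the VCF FILTER column carries the
    outcomes. Strand bias is skipped entirely in amplicon mode, where reads
    inherit their strand from the amplicon design.
    """
    blacklist = list(config.blacklist)
    for record in calls:
        flags: list[str] = []
        covered = [
            rep.get(record.chrom, record.pos)
            for rep in reps.replicates
        ]
        covered = [o for o in covered if o.depth > 0]
        if any(
            o.alt_counts.get(record.alt, 0) < config.min_alt_reads_per_rep
            for o in covered
        ):
            flags.append("min_alt_reads")
        if any(o.depth < config.min_depth for o in covered):
            flags.append("low_depth")
        if config.mode != "amplicon" and _strand_bias_flagged(
            reps, record, config.strand_bias_p
        ):
            flags.append("strand_bias")
        # triallelic consistency: a competing alt at >= ratio * candidate VAF
        # in every covered replicate marks error accumulation
        competing = [
            any(
                other != record.alt
                and o.vaf(other) >= config.triallelic_vaf_ratio * o.vaf(record.alt)
                for other in o.alt_counts
            )
            for o in covered
            if o.alt_counts.get(record.alt, 0) > 0
        ]
        if competing and all(competing):
            flags.append("triallelic")
        for region in blacklist:
            if (
                region.chrom == record.chrom
                and region.start + 1 - config.blacklist_pad
                <= record.pos
                <= region.end + config.blacklist_pad
            ):
                flags.append("blacklist")
                break
        record.filters = flags
    return calls


# ---------------------------------------------------------------------------
# Convenience pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    reps: ReplicateSet,
    config: Optional[CallerConfig] = None,
    profile: Optional[ErrorProfile] = None,
    target_bp: Optional[int] = None,
) -> tuple[list[CallRecord], ErrorProfile, Priors]:
    """Profile (unless a fitted sidecar is supplied), score, and post-filter.

    Returns every scored record; candidates are those with ``s > 0`` and
    calls those additionally passing all post-filters.
    """
    config = config or CallerConfig()
    mask: set = set()
    if reps.control is not None and reps.control.sites:
        mask = build_germline_mask(reps.control)
    if profile is None:
        profile = fit_error_profile(reps, germline_mask=mask, target_bp=target_bp)
    priors = compute_priors(config.f_v, profile.f_be)
    records = call_variants(reps, profile, config, priors, germline_mask=mask)
    apply_postfilters(records, reps, config)
    return records, profile, priors


AUDIT_HEADER = (
    "chrom\tpos\tref\talt\tsubstitution\tS\tmu_hat\tlambda\t"
    "depths\talt_counts\tx_be\tfilters\tcalled"
)


def write_audit_table(calls: Sequence[CallRecord], out_path: str) -> None:
    """TSV of every scored site (called and rejected) for debugging."""
    with open(out_path, "w") as fh:
        fh.write(AUDIT_HEADER + "\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.ref}\t{c.alt}\t{c.substitution}\t"
                f"{c.s:.6f}\t{c.mu_hat:.6g}\t{c.lambda_be:.6g}\t"
                f"{','.join(str(e.n) for e in c.evidence)}\t"
                f"{','.join(str(e.b) for e in c.evidence)}\t"
                f"{','.join(f'{e.x_be:.6g}' for e in c.evidence)}\t"
                f"{';'.join(c.filters) or '.'}\t{int(c.called)}\n"
            )
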