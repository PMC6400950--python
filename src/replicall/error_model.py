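"""Background-error model (M0) estimation.

Background errors are mismatches introduced before sequencing (PCR damage,
oxidation, other library-preparation artifacts). They carry high base-call
qualities, so quality-aware filtering cannot see them. The estimator here
quantifies them per site with the mismatch over-representation score

    MOS = b_BE = b - sum_l 10^(-q_l / 10),

i.e. the observed alt read count minus the count explained by sequencing
error alone, and profiles the adjusted VAF x_BE = b_BE / n across a target
to fit one exponential background-error distribution per substitution type.
The fraction of target positions with b_BE > 0 (f_BE) and the user-supplied
somatic mutation frequency f_v yield the model priors
phi_v = f_v / (f_v + f_BE) and phi_BE = 1 - phi_v.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .pileup_io import (
    PileupSeries,
    ReplicateSet,
    SiteObservation,
    SUBSTITUTION_TYPES,
    normalize_substitution,
)

__all__ = [
    "AdjustedObservation",
    "ErrorProfile",
    "Priors",
    "expected_sequencing_errors",
    "mos",
    "adjust_observation",
    "collect_profile_sites",
    "estimate_f_be",
    "fit_exponential",
    "fit_error_profile",
    "error_likelihood",
    "log_error_likelihood",
    "compute_priors",
    "build_germline_mask",
]

#: Minimum per-type sample count before falling back to the pooled fit.
DEFAULT_MIN_SAMPLES = 50

#: Profile self-masking removes putative shared variants: sites whose x_BE
#: exceeds this quantile of the type's profile in every replicate.
SELF_MASK_QUANTILE = 0.999


def expected_sequencing_errors(quals: Sequence[int]) -> float:
    """Expected alt-read count from base-call (sequencing) error alone:
    ``sum_l 10^(-q_l/10)``. Returns 0.0 for an empty list."""
    if len(quals) == 0:
        return 0.0
    q = np.asarray(quals, dtype=float)
    if np.any(q < 0):
        raise ValueError("negative Phred quality")
    return float(np.power(10.0, -q / 10.0).sum())


def mos(site: SiteObservation, alt: str) -> float:
    """Mismatch over-representation score b_BE = b - b_SE for ``alt``."""
    b = site.alt_counts.get(alt, 0)
    if b == 0:
        return 0.0
    return b - expected_sequencing_errors(site.alt_quals[alt])


@dataclass(frozen=True)
class AdjustedObservation:
    """Sequencing-error-adjusted evidence for one allele at one site."""

    b: int          # alt read count
    b_se: float     # expected sequencing-error reads
    b_be: float     # MOS; may be <= 0
    x_be: float     # adjusted VAF b_BE / n (un-clamped)


def adjust_observation(site: SiteObservation, alt: str) -> AdjustedObservation:
    b = site.alt_counts.get(alt, 0)
    b_se = expected_sequencing_errors(site.alt_quals.get(alt, [])) if b else 0.0
    b_be = b - b_se
    x_be = b_be / site.depth if site.depth > 0 else 0.0
    return AdjustedObservation(b=b, b_se=b_se, b_be=b_be, x_be=x_be)


# ---------------------------------------------------------------------------
# Profile construction
# ---------------------------------------------------------------------------

def _profile_records(
    reps: ReplicateSet,
    germline_mask: frozenset | set = frozenset(),
    somatic_mask: frozenset | set = frozenset(),
) -> list[list[tuple[tuple[str, int], str, float]]]:
    """Per replicate: [(position-key, substitution-type, x_BE), ...] for every
    profile-eligible site (>=1 alt read, b_BE > 0, unmasked), binned by the
    modal alt allele."""
    excluded = set(germline_mask) | set(somatic_mask)
    out = []
    for rep in reps.replicates:
        records: list[tuple[tuple[str, int], str, float]] = []
        for key, site in rep.sites.items():
            if key in excluded or not site.alt_counts or site.depth == 0:
                continue
            alt = site.modal_alt()
            adj = adjust_observation(site, alt)
            if adj.b_be <= 0:
                continue
            records.append((key, normalize_substitution(site.ref, alt), adj.x_be))
        out.append(records)
    return out


def collect_profile_sites(
    reps: ReplicateSet,
    germline_mask: frozenset | set = frozenset(),
    somatic_mask: frozenset | set = frozenset(),
) -> list[dict[str, list[float]]]:
    """Adjusted-VAF profile samples, one ``{substitution type: [x_BE, ...]}``
    map per replicate.

    Sites contribute only when they carry at least one alt read with
    b_BE > 0 and are in neither mask (masked sites are likely genuine
    germline or somatic variants, which would contaminate the error
    profile). Each site contributes its modal alt allele.
    """
    if not any(rep.sites for rep in reps.replicates):
        raise ValueError("cannot profile an empty target")
    out = []
    for records in _profile_records(reps, germline_mask, somatic_mask):
        by_type: dict[str, list[float]] = {t: [] for t in SUBSTITUTION_TYPES}
        for _, subst, x_be in records:
            by_type[subst].append(x_be)
        out.append(by_type)
    return out


def estimate_f_be(
    reps: ReplicateSet,
    germline_mask: frozenset | set = frozenset(),
    somatic_mask: frozenset | set = frozenset(),
    target_bp: Optional[int] = None,
) -> float:
    """Fraction of target positions with b_BE > 0, computed per replicate
    and then averaged. Masked sites leave the numerator but stay in the
    denominator, which is the full target length (zero-coverage positions
    can never satisfy b_BE > 0, a conservative choice)."""
    if target_bp is None:
        target_bp = reps.target_bp()
    if target_bp <= 0:
        raise ValueError("zero-length target")
    excluded = set(germline_mask) | set(somatic_mask)
    fractions = []
    for rep in reps.replicates:
        hits = 0
        for key, site in rep.sites.items():
            if key in excluded or not site.alt_counts or site.depth == 0:
                continue
            if any(mos(site, alt) > 0 for alt in site.alt_counts):
                hits += 1
        fractions.append(hits / target_bp)
    return float(np.mean(fractions))


def fit_exponential(samples: Sequence[float]) -> float:
    """Closed-form exponential MLE: lambda = 1 / mean(samples).

    Identical to iterative ML fitting of the exponential family up to
    numerics; samples must be positive adjusted VAFs.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot fit an exponential to zero samples")
    if np.any(arr <= 0):
        raise ValueError("profile samples must be positive")
    return float(1.0 / arr.mean())


@dataclass
class ErrorProfile:
    """Fitted background-error model for one replicate set: per-substitution
    exponential rates (units 1/VAF), per-type sample counts, the pooled
    fallback rate, and the background-error site fraction f_BE."""

    lambda_by_type: dict[str, float]
    n_samples_by_type: dict[str, int]
    f_be: float
    pooled_lambda: Optional[float] = None
    fallback_types: set[str] = field(default_factory=set)

    def lambda_for(self, substitution: str) -> float:
        lam = self.lambda_by_type.get(substitution)
        if lam is None:
            if self.pooled_lambda is None:
                raise KeyError(
                    f"no fitted rate for {substitution} and no pooled fallback"
                )
            return self.pooled_lambda
        return lam

    def to_json(self, path: str) -> None:
        payload = {
            "lambda_by_type": self.lambda_by_type,
            "n_samples_by_type": self.n_samples_by_type,
            "f_be": self.f_be,
            "pooled_lambda": self.pooled_lambda,
            "fallback_types": sorted(self.fallback_types),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "ErrorProfile":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            lambda_by_type=dict(payload["lambda_by_type"]),
            n_samples_by_type={k: int(v) for k, v in payload["n_samples_by_type"].items()},
            f_be=float(payload["f_be"]),
            pooled_lambda=payload.get("pooled_lambda"),
            fallback_types=set(payload.get("fallback_types", [])),
        )


def _fit_from_samples(
    by_type_per_rep: list[dict[str, list[float]]],
    f_be: float,
    min_samples: int,
) -> ErrorProfile:
    pooled_all: list[float] = []
    merged: dict[str, list[float]] = {t: [] for t in SUBSTITUTION_TYPES}
    for by_type in by_type_per_rep:
        for subst, values in by_type.items():
            merged[subst].extend(values)
            pooled_all.extend(values)
    if not pooled_all:
        raise ValueError("no profile samples with b_BE > 0 on the target")
    pooled_lambda = fit_exponential(pooled_all)
    lambda_by_type: dict[str, float] = {}
    n_samples: dict[str, int] = {}
    fallback: set[str] = set()
    for subst in SUBSTITUTION_TYPES:
        values = merged[subst]
        n_samples[subst] = len(values)
        if len(values) >= min_samples:
            lambda_by_type[subst] = fit_exponential(values)
        else:
            lambda_by_type[subst] = pooled_lambda
            fallback.add(subst)
    return ErrorProfile(
        lambda_by_type=lambda_by_type,
        n_samples_by_type=n_samples,
        f_be=f_be,
        pooled_lambda=pooled_lambda,
        fallback_types=fallback,
    )


def fit_error_profile(
    reps: ReplicateSet,
    germline_mask: frozenset | set = frozenset(),
    somatic_mask: frozenset | set = frozenset(),
    target_bp: Optional[int] = None,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    self_mask: bool = True,
) -> ErrorProfile:
    """Full M0 estimation: collect profile sites, fit per-type exponentials,
    estimate f_BE, then (once) remove likely shared variants and refit.

    The self-mask removes positions whose x_BE exceeds the type profile's
    99.9th percentile in *all* replicates — evidence reproducibly too strong
    to be background error — standing in for exclusion of sites jointly
    called by an external somatic caller across replicates.
    """
    records = _profile_records(reps, germline_mask, somatic_mask)
    if not any(records):
        raise ValueError("no profile samples with b_BE > 0 on the target")

    def to_by_type(recs):
        out = []
        for rep_records in recs:
            by_type = {t: [] for t in SUBSTITUTION_TYPES}
            for _, subst, x_be in rep_records:
                by_type[subst].append(x_be)
            out.append(by_type)
        return out

    f_be = estimate_f_be(reps, germline_mask, somatic_mask, target_bp)
    profile = _fit_from_samples(to_by_type(records), f_be, min_samples)
    if not self_mask or reps.k < 2:
        return profile

    # one refit pass with reproducibly-extreme sites removed
    cutoffs: dict[str, float] = {}
    for subst in SUBSTITUTION_TYPES:
        values = [x for rep in to_by_type(records) for x in rep[subst]]
        if values:
            cutoffs[subst] = float(np.quantile(values, SELF_MASK_QUANTILE))
    extreme_per_rep = []
    for rep_records in records:
        extreme_per_rep.append(
            {key for key, subst, x in rep_records if x > cutoffs.get(subst, math.inf)}
        )
    shared_extreme = set.intersection(*extreme_per_rep) if extreme_per_rep else set()
    if not shared_extreme:
        return profile
    somatic = set(somatic_mask) | shared_extreme
    records = _profile_records(reps, germline_mask, somatic)
    f_be = estimate_f_be(reps, germline_mask, somatic, target_bp)
    return _fit_from_samples(to_by_type(records), f_be, min_samples)


# ---------------------------------------------------------------------------
# Likelihood and priors
# ---------------------------------------------------------------------------

def error_likelihood(x_be: float, lam: float) -> float:
    """Exponential M0 density ``lam * exp(-lam * x)``.

    Adjusted VAFs can be <= 0 when base qualities over-explain the
    mismatches; the density is then evaluated at 0 (i.e. returns ``lam``),
    which keeps the likelihood finite and monotone.
    """
    if lam <= 0:
        raise ValueError("exponential rate must be positive")
    if x_be <= 0:
        return lam
    return lam * math.exp(-lam * x_be)


def log_error_likelihood(x_be: float, lam: float) -> float:
    if lam <= 0:
        raise ValueError("exponential rate must be positive")
    if x_be <= 0:
        return math.log(lam)
    return math.log(lam) - lam * x_be


@dataclass(frozen=True)
class Priors:
    """Prior probabilities that a mismatch-bearing site is a variant
    (phi_v) or a background error (phi_BE)."""

    f_v: float
    f_be: float
    phi_v: float
    phi_be: float


def compute_priors(f_v: float, f_be: float) -> Priors:
    """phi_v = f_v / (f_v + f_BE); phi_BE is its complement, so the two sum
    to 1 exactly."""
    if f_v <= 0:
        raise ValueError("somatic mutation frequency f_v must be positive")
    if f_be < 0:
        raise ValueError("f_BE cannot be negative")
    total = f_v + f_be
    phi_v = f_v / total
    return Priors(f_v=f_v, f_be=f_be, phi_v=phi_v, phi_be=1.0 - phi_v)


# ---------------------------------------------------------------------------
# Germline masking
# ---------------------------------------------------------------------------

def build_germline_mask(
    control: PileupSeries,
    vaf_threshold: float = 0.2,
    min_depth: int = 20,
    extra_positions: Iterable[tuple[str, int]] = (),
) -> set[tuple[str, int]]:
    """Positions whose matched-control alt VAF reaches ``vaf_threshold`` at
    depth >= ``min_depth`` (germline het/hom signal). Optionally unioned
    with user-supplied positions (e.g. from a germline VCF)."""
    if not control.sites:
        raise ValueError("control series is empty")
    mask: set[tuple[str, int]] = set(extra_positions)
    for key, site in control.sites.items():
        if site.depth < min_depth or not site.alt_counts:
            continue
        if max(site.vaf(alt) for alt in site.alt_counts) >= vaf_threshold:
            mask.add(key)
    return mask


def read_vcf_positions(vcf_path: str) -> set[tuple[str, int]]:
    """1-based (chrom, pos) keys from a (germline) VCF."""
    positions: set[tuple[str, int]] = set()
    with open(vcf_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split("\t")
            positions.add((fields[0], int(fields[1])))
    return positions
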