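"""Primitive replicate-combination strategies and performance evaluation.

Intersection ("call-and-validate"), union, and count-level merge are the
straightforward ways to use replicates with a single-sample caller; they are
the baselines the joint model is compared against. A naive threshold caller
(call when VAF >= min_vaf and alt reads >= min_alt) stands in for a
conventional single-sample somatic caller. Its default operating point,
min_vaf = 1%, matches the common reportable-VAF floor of deep targeted
panels and the effective stringency of widely used callers at ~1000x.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .pileup_io import PileupSeries, ReplicateSet, SiteObservation

__all__ = [
    "CallSet",
    "PerformanceReport",
    "intersect_calls",
    "union_calls",
    "merge_pileups",
    "naive_caller",
    "evaluate_calls",
    "match_sensitivity",
]

CallKey = tuple[str, int, str, str]  # (chrom, pos, ref, alt)


class CallSet:
    """A set of (chrom, pos, ref, alt) call keys with optional scores."""

    def __init__(
        self,
        keys: Iterable[CallKey] = (),
        scores: Optional[Mapping[CallKey, float]] = None,
    ) -> None:
        self.keys: set[CallKey] = set(keys)
        self.scores: dict[CallKey, float] = dict(scores or {})

    @classmethod
    def from_records(cls, records, passing_only: bool = True) -> "CallSet":
        """Build from caller CallRecords; by default keep candidate calls
        (S > 0, no filter flags)."""
        keys = []
        scores = {}
        for r in records:
            if passing_only and not r.called:
                continue
            keys.append(r.key)
            scores[r.key] = r.s
        return cls(keys, scores)

    def positions(self) -> set[tuple[str, int]]:
        return {(c, p) for c, p, _, _ in self.keys}

    def __len__(self) -> int:
        return len(self.keys)

    def __contains__(self, key: CallKey) -> bool:
        return key in self.keys

    def __eq__(self, other) -> bool:
        return isinstance(other, CallSet) and self.keys == other.keys

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\n")
            for chrom, pos, ref, alt in sorted(self.keys):
                fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")

    @classmethod
    def read_tsv(cls, path: str) -> "CallSet":
        keys = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("chrom"):
                raise ValueError(f"{path}: missing call-set header")
            for line in fh:
                if not line.strip():
                    continue
                chrom, pos, ref, alt = line.rstrip("\n").split("\t")
                keys.append((chrom, int(pos), ref, alt))
        return cls(keys)


def intersect_calls(callsets: Sequence[CallSet]) -> CallSet:
    """Keys present in every call set. Positions where the sets disagree on
    the alt allele are conflicts and are discarded outright."""
    if len(callsets) < 2:
        raise ValueError("intersection needs at least two call sets")
    common = set.intersection(*(cs.keys for cs in callsets))
    conflicted = set()
    for key in common:
        chrom, pos, _, alt = key
        for cs in callsets:
            if any(
                k[0] == chrom and k[1] == pos and k[3] != alt for k in cs.keys
            ):
                conflicted.add(key)
                break
    return CallSet(common - conflicted)


def union_calls(callsets: Sequence[CallSet]) -> CallSet:
    """Set union on call keys."""
    keys: set[CallKey] = set()
    for cs in callsets:
        keys |= cs.keys
    return CallSet(keys)


def merge_pileups(reps: ReplicateSet) -> PileupSeries:
    """Count-level analog of merging replicate BAMs: per-site depths and
    alt counts are summed and alt qualities concatenated, enabling
    single-sample scoring of the pooled evidence."""
    positions: set[tuple[str, int]] = set()
    for rep in reps.replicates:
        positions.update(rep.sites)
    uniform = None
    if all(rep.uniform_depth is not None for rep in reps.replicates):
        uniform = sum(rep.uniform_depth for rep in reps.replicates)
    merged = PileupSeries(
        regions=reps.regions, uniform_depth=uniform, name="merged"
    )
    for chrom, pos in sorted(positions):
        ref = "N"
        depth = 0
        alt_counts: dict[str, int] = {}
        alt_quals: dict[str, list[int]] = {}
        for rep in reps.replicates:
            obs = rep.get(chrom, pos)
            if obs.ref != "N":
                if ref != "N" and obs.ref != ref:
                    raise ValueError(
                        f"reference mismatch at {chrom}:{pos}: {ref} vs {obs.ref}"
                    )
                ref = obs.ref
            depth += obs.depth
            for alt, count in obs.alt_counts.items():
                alt_counts[alt] = alt_counts.get(alt, 0) + count
                alt_quals.setdefault(alt, []).extend(obs.alt_quals[alt])
        if ref == "N":
            continue
        merged.add(
            SiteObservation(chrom, pos, ref, depth, alt_counts, alt_quals)
        )
    return merged


def naive_caller(
    series: PileupSeries,
    min_vaf: float = 0.01,
    min_alt: int = 2,
    min_depth: int = 0,
) -> CallSet:
    """Single-sample threshold caller: call every allele with
    x >= min_vaf and b >= min_alt (and depth >= min_depth)."""
    keys = []
    scores = {}
    for site in series:
        if site.depth < min_depth or site.depth == 0:
            continue
        for alt, b in site.alt_counts.items():
            vaf = b / site.depth
            if vaf >= min_vaf and b >= min_alt:
                key = (site.chrom, site.pos, site.ref, alt)
                keys.append(key)
                scores[key] = vaf
    return CallSet(keys, scores)


@dataclass(frozen=True)
class PerformanceReport:
    """Exact-key comparison of calls against truth: counts, sensitivity,
    precision, F-score, and false positives per megabase of target."""

    tp: int
    fp: int
    fn: int
    sensitivity: float
    precision: float
    f_score: float
    fpr_per_mb: float
    target_bp: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    def table(self) -> str:
        return (
            f"TP {self.tp}  FP {self.fp}  FN {self.fn}\n"
            f"sensitivity {self.sensitivity:.4f}  precision {self.precision:.4f}  "
            f"F-score {self.f_score:.4f}  FPR/Mb {self.fpr_per_mb:.2f}"
        )


def evaluate_calls(
    calls: CallSet, truth_keys: Iterable[CallKey], target_bp: int
) -> PerformanceReport:
    """Compare on exact (chrom, pos, ref, alt) keys. Zero denominators
    yield 0.0 by convention."""
    if target_bp <= 0:
        raise ValueError("target size must be positive")
    truth = set(truth_keys)
    tp = len(calls.keys & truth)
    fp = len(calls.keys - truth)
    fn = len(truth - calls.keys)
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    denom = sensitivity + precision
    f_score = 2 * sensitivity * precision / denom if denom else 0.0
    return PerformanceReport(
        tp=tp,
        fp=fp,
        fn=fn,
        sensitivity=sensitivity,
        precision=precision,
        f_score=f_score,
        fpr_per_mb=fp / (target_bp / 1e6),
        target_bp=target_bp,
    )


def match_sensitivity(
    series: PileupSeries,
    truth_keys: Iterable[CallKey],
    target_sensitivity: float,
    depth: int,
    min_alt: int = 1,
) -> tuple[CallSet, float]:
    """Tune the naive caller's VAF threshold on one replicate so that its
    sensitivity is the smallest value >= ``target_sensitivity`` (fall back
    to the most permissive threshold if none reaches it). Returns the call
    set and the chosen threshold. Used for matched-sensitivity FPR
    comparisons."""
    truth = set(truth_keys)
    if not truth:
        raise ValueError("cannot match sensitivity against an empty truth set")
    # alt-read support of each truth key in this replicate
    support = []
    for site in series:
        for alt, b in site.alt_counts.items():
            if (site.chrom, site.pos, site.ref, alt) in truth:
                support.append(b)
    support.sort(reverse=True)
    chosen = 1
    for b_min in range(max(support, default=1), 0, -1):
        sens = sum(1 for b in support if b >= max(b_min, min_alt)) / len(truth)
        chosen = b_min
        if sens >= target_sensitivity:
            break
    threshold = chosen / depth
    return naive_caller(series, min_vaf=threshold, min_alt=min_alt), threshold
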