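"""Shared fixtures: hand-built SAM/BAM alignments, flat error profiles, and
one session-scoped end-to-end simulation reused by the expensive tests."""

from __future__ import annotations

import pytest
from hypothesis import settings

from replicall import (
    CallerConfig,
    CallSet,
    ReplicateSet,
    SimulationConfig,
    evaluate_calls,
    simulate_replicates,
)
from replicall.baselines import intersect_calls, match_sensitivity, naive_caller
from replicall.caller import run_pipeline
from replicall.error_model import ErrorProfile
from replicall.pileup_io import SUBSTITUTION_TYPES
from replicall.simulator import spectrum_preset

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


def flat_profile(lam: float = 700.0, f_be: float = 0.01) -> ErrorProfile:
    """An error profile with one exponential rate for all six classes."""
    return ErrorProfile(
        lambda_by_type={t: lam for t in SUBSTITUTION_TYPES},
        n_samples_by_type={t: 10_000 for t in SUBSTITUTION_TYPES},
        f_be=f_be,
        pooled_lambda=lam,
    )


@pytest.fixture
def profile700() -> ErrorProfile:
    return flat_profile(700.0, 0.01)


# ---------------------------------------------------------------------------
# SAM fixtures
# ---------------------------------------------------------------------------

SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:300\n"


def sam_line(
    name: str,
    flag: int,
    pos: int,
    mapq: int,
    seq: str,
    quals: str,
    cigar: str | None = None,
    rnext: str = "*",
    pnext: int = 0,
    tlen: int = 0,
) -> str:
    cigar = cigar or f"{len(seq)}M"
    return (
        f"{name}\t{flag}\tchr1\t{pos}\t{mapq}\t{cigar}\t{rnext}\t{pnext}\t"
        f"{tlen}\t{seq}\t{quals}\n"
    )


@pytest.fixture
def reference_fasta(tmp_path):
    """chr1: 300 bp of 'A'."""
    path = tmp_path / "ref.fa"
    path.write_text(">chr1\n" + "A" * 300 + "\n")
    import pysam

    pysam.faidx(str(path))
    return str(path)


@pytest.fixture
def make_bam(tmp_path):
    """Write SAM text, convert to sorted+indexed BAM, return the path."""
    import pysam

    def _make(sam_body: str, name: str = "reads") -> str:
        sam_path = tmp_path / f"{name}.sam"
        bam_path = tmp_path / f"{name}.bam"
        sam_path.write_text(SAM_HEADER + sam_body)
        pysam.view("-b", "-o", str(bam_path), str(sam_path), catch_stdout=False)
        pysam.index(str(bam_path))
        return str(bam_path)

    return _make


# ---------------------------------------------------------------------------
# End-to-end simulation shared by the expensive tests
# ---------------------------------------------------------------------------

E2E_SEED = 20190305


@pytest.fixture(scope="session")
def end_to_end():
    """One full joint-calling experiment at study conditions: duplicate
    library replicates, 1% spike-in VAF, 1000x depth, amplicon error
    spectrum, 100 kb target, fixed seed."""
    lambdas, f_be = spectrum_preset("amplicon_pcr")
    config = SimulationConfig(
        seed=E2E_SEED,
        target_bp=100_000,
        depth=1000,
        k=2,
        true_vafs=(0.01,),
        n_true_sites=100,
        lambda_by_type=lambdas,
        f_be=f_be,
    )
    reps, truth = simulate_replicates(config)
    # the realized mutation rate of the spiked target serves as f_v, as one
    # would supply for a benchmark with a deliberately mutation-dense target
    caller_config = CallerConfig(
        f_v=config.n_true_sites / config.target_bp, mode="amplicon"
    )
    records, profile, priors = run_pipeline(
        reps, caller_config, target_bp=config.target_bp
    )
    joint = CallSet.from_records(records)
    joint_report = evaluate_calls(joint, truth.keys(), config.target_bp)
    intersection = intersect_calls([naive_caller(r) for r in reps.replicates])
    intersection_report = evaluate_calls(
        intersection, truth.keys(), config.target_bp
    )
    matched_calls, matched_threshold = match_sensitivity(
        reps.replicates[0], truth.keys(), joint_report.sensitivity, config.depth
    )
    matched_report = evaluate_calls(matched_calls, truth.keys(), config.target_bp)
    return {
        "config": config,
        "caller_config": caller_config,
        "reps": reps,
        "truth": truth,
        "records": records,
        "profile": profile,
        "priors": priors,
        "joint": joint_report,
        "intersection": intersection_report,
        "matched_naive": matched_report,
        "matched_threshold": matched_threshold,
    }
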