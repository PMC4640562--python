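"""Monte-Carlo verification of the CLS test's operating characteristics.

The generative model has three knobs mapping one-to-one onto the
quantities the test calibrates:

* ``true_shared_rate`` — probability a locus in the pair is truly clonal
  (0 for independent pairs; around 15–20% for clonal pairs);
* ``detection_sensitivity_a`` / ``_b`` — probability a truly shared
  mutation is detected in each tumor (low tumor cellularity depresses
  this); a shared mutation detected in exactly one tumor degrades to a
  private call, and one detected in neither drops out of the observed
  total;
* ``fp_shared_rate`` — probability an unshared locus is miscalled as
  shared (technical artifacts plus recurrent drivers; this is what p0
  bounds).

``estimate_operating_characteristics`` replays the CLS decision over many
simulated pairs to measure empirical type-I error (null configuration) or
power (clonal configuration).

``generate_fixture_trio`` emits full per-locus read-evidence tables that
realize requested shared/private/rejected counts under the default HC
filter, for end-to-end pipeline tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cls_test import TestParams
from .exceptions import GenerationError, ValidationError
from .hc_filter import REASONS, HCFilterParams, build_profile
from .study_design import critical_value
from .variant_io import LocusEvidence, LocusKey, SampleEvidence

__all__ = [
    "SimParams",
    "OperatingCharacteristics",
    "simulate_pair",
    "estimate_operating_characteristics",
    "generate_fixture_trio",
]


@dataclass(frozen=True)
class SimParams:
    """Configuration of the tumor-pair simulator."""

    n_total_range: tuple[int, int] = (44, 44)
    true_shared_rate: float = 0.0
    fp_shared_rate: float = 0.0
    detection_sensitivity_a: float = 1.0
    detection_sensitivity_b: float = 1.0
    seed: int = 0
    reps: int = 10_000

    def __post_init__(self) -> None:
        lo, hi = self.n_total_range
        if not 1 <= lo <= hi:
            raise ValidationError(f"empty or invalid n_total_range: {self.n_total_range}")
        for name in ("true_shared_rate", "fp_shared_rate",
                     "detection_sensitivity_a", "detection_sensitivity_b"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.reps < 1:
            raise ValidationError(f"reps must be >= 1, got {self.reps}")


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Empirical rejection rate of the CLS test with its Monte-Carlo error."""

    rejection_fraction: float
    mc_stderr: float
    reps: int
    params_echo: SimParams
    test_params_echo: TestParams

    def to_dict(self) -> dict:
        return {
            "rejection_fraction": self.rejection_fraction,
            "mc_stderr": self.mc_stderr,
            "reps": self.reps,
            "sim_params": {
                "n_total_range": list(self.params_echo.n_total_range),
                "true_shared_rate": self.params_echo.true_shared_rate,
                "fp_shared_rate": self.params_echo.fp_shared_rate,
                "detection_sensitivity_a": self.params_echo.detection_sensitivity_a,
                "detection_sensitivity_b": self.params_echo.detection_sensitivity_b,
                "seed": self.params_echo.seed,
                "reps": self.params_echo.reps,
            },
            "test_params": {
                "p0": self.test_params_echo.p0,
                "alpha": self.test_params_echo.alpha,
                "pa": self.test_params_echo.pa,
            },
        }


def simulate_pair(params: SimParams, rng: np.random.Generator) -> tuple[int, int]:
    """Draw one simulated tumor pair; returns observed (X, n).

    The drawn total is thinned of truly shared mutations detected in
    neither tumor (they are observed nowhere); a shared mutation detected
    in exactly one tumor is counted as private, so it lowers X but not n.
    """
    lo, hi = params.n_total_range
    n_drawn = int(rng.integers(lo, hi + 1))
    n_true_shared = rng.binomial(n_drawn, params.true_shared_rate)
    sa, sb = params.detection_sensitivity_a, params.detection_sensitivity_b
    both, a_only, b_only, neither = rng.multinomial(
        n_true_shared,
        [sa * sb, sa * (1 - sb), (1 - sa) * sb, (1 - sa) * (1 - sb)],
    )
    n_unshared = n_drawn - n_true_shared
    fp_shared = rng.binomial(n_unshared, params.fp_shared_rate)
    X = int(both + fp_shared)
    n_obs = int(n_drawn - neither)
    return X, n_obs


def estimate_operating_characteristics(
    sim_params: SimParams, test_params: TestParams = TestParams()
) -> OperatingCharacteristics:
    """Empirical rejection fraction of the CLS decision over ``reps`` pairs.

    A pair is rejected (called clonal) when X >= c(n, p0, alpha); critical
    values are cached per observed n.  Fully reproducible from
    ``sim_params.seed``.
    """
    rng = np.random.default_rng(sim_params.seed)
    crit_cache: dict[int, int] = {}
    rejections = 0
    for _ in range(sim_params.reps):
        X, n = simulate_pair(sim_params, rng)
        if n == 0:
            continue
        c = crit_cache.get(n)
        if c is None:
            c = crit_cache[n] = critical_value(n, test_params.p0, test_params.alpha)
        if X >= c:
            rejections += 1
    f = rejections / sim_params.reps
    return OperatingCharacteristics(
        rejection_fraction=f,
        mc_stderr=math.sqrt(f * (1 - f) / sim_params.reps),
        reps=sim_params.reps,
        params_echo=sim_params,
        test_params_echo=test_params,
    )


# ---------------------------------------------------------------------------
# evidence fixture generation
# ---------------------------------------------------------------------------

_DEFAULT_FILTER = HCFilterParams()


def _passing_base(rng: np.random.Generator, pos: int) -> dict:
    """Evidence fields that pass every default HC rule (shared archetype)."""
    ref, alt = [str(b) for b in rng.choice(list("ACGT"), size=2, replace=False)]
    g_depth = int(rng.integers(25, 61))
    depth_a = int(rng.integers(45, 151))
    depth_b = int(rng.integers(45, 151))
    return {
        "key": LocusKey("chr1", pos, ref, alt),
        "germline": SampleEvidence(g_depth, 0, g_depth, called=False),
        "tumor_a": SampleEvidence(depth_a, int(0.4 * depth_a), depth_a, called=True),
        "tumor_b": SampleEvidence(depth_b, int(0.4 * depth_b), depth_b, called=True),
        "in_dbsnp": False,
    }


def _uncalled(ev: SampleEvidence, rng: np.random.Generator) -> SampleEvidence:
    depth = int(rng.integers(45, 151))
    return SampleEvidence(depth, 0, depth, called=False)


def _break_rule(fields: dict, reason: str, rng: np.random.Generator) -> dict:
    """Mutate a passing record so it fails exactly the requested rule."""
    if reason == "dbsnp":
        fields["in_dbsnp"] = True
    elif reason == "germline_coverage":
        hq = int(rng.integers(0, _DEFAULT_FILTER.germline_min_hq_depth))
        fields["germline"] = SampleEvidence(max(hq, 0), 0, hq, called=False)
    elif reason == "germline_alt_reads":
        # 2 alt reads at high depth: fails the read-count rule, not the fraction rule
        fields["germline"] = SampleEvidence(100, 2, 100, called=False)
    elif reason == "germline_alt_fraction":
        # 1 alt read in 16 reads = 6.25% >= 5%, but read count still <= 1
        fields["germline"] = SampleEvidence(16, 1, 16, called=False)
    elif reason == "tumor_coverage":
        depth = int(rng.integers(5, _DEFAULT_FILTER.tumor_min_depth))
        fields["tumor_b"] = SampleEvidence(depth, int(0.4 * depth), depth, called=True)
    elif reason == "no_tumor_call":
        fields["tumor_a"] = _uncalled(fields["tumor_a"], rng)
        fields["tumor_b"] = _uncalled(fields["tumor_b"], rng)
    else:
        raise GenerationError(f"unknown rejection reason {reason!r}; known: {REASONS}")
    return fields


def generate_fixture_trio(
    n_shared: int,
    n_private_a: int,
    n_private_b: int,
    n_rejected_by_reason: dict[str, int] | None = None,
    seed: int = 0,
) -> list[LocusEvidence]:
    """Emit an evidence table realizing exact profile counts under default filters.

    The returned table, run through :func:`clstest.hc_filter.build_profile`
    with default :class:`HCFilterParams`, yields exactly ``n_shared`` shared,
    ``n_private_a``/``n_private_b`` private loci and the requested rejection
    tallies; this is verified internally before returning.
    """
    if min(n_shared, n_private_a, n_private_b) < 0:
        raise GenerationError("counts must be non-negative")
    n_rejected_by_reason = dict(n_rejected_by_reason or {})
    if any(v < 0 for v in n_rejected_by_reason.values()):
        raise GenerationError("rejection counts must be non-negative")
    rng = np.random.default_rng(seed)
    records: list[LocusEvidence] = []
    pos = 0

    def emit(fields: dict) -> None:
        records.append(LocusEvidence(**fields))

    for _ in range(n_shared):
        pos += 1
        emit(_passing_base(rng, pos))
    for _ in range(n_private_a):
        pos += 1
        fields = _passing_base(rng, pos)
        fields["tumor_b"] = _uncalled(fields["tumor_b"], rng)
        emit(fields)
    for _ in range(n_private_b):
        pos += 1
        fields = _passing_base(rng, pos)
        fields["tumor_a"] = _uncalled(fields["tumor_a"], rng)
        emit(fields)
    for reason, count in n_rejected_by_reason.items():
        for _ in range(count):
            pos += 1
            emit(_break_rule(_passing_base(rng, pos), reason, rng))

    profile = build_profile(records, _DEFAULT_FILTER)
    expected_log = {k: v for k, v in n_rejected_by_reason.items() if v}
    if (profile.X != n_shared or len(profile.private_a) != n_private_a
            or len(profile.private_b) != n_private_b
            or profile.filter_log != expected_log):
        raise GenerationError(
            "generated fixture does not realize the requested profile "
            f"(got X={profile.X}, a={len(profile.private_a)}, "
            f"b={len(profile.private_b)}, log={profile.filter_log})"
        )
    return records


def simulate_pair_with_fixture(
    params: SimParams, rng: np.random.Generator
) -> tuple[int, int, list[LocusEvidence]]:
    """Like :func:`simulate_pair`, also emitting an evidence table realizing (X, n).

    Observed-shared loci become shared records; the remaining observed loci
    are split evenly between the two tumors as private records.
    """
    X, n = simulate_pair(params, rng)
    n_private = n - X
    fixture_seed = int(rng.integers(0, 2**31 - 1))
    table = generate_fixture_trio(
        X, n_private - n_private // 2, n_private // 2, seed=fixture_seed
    )
    return X, n, table
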