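"""The Clonal Likelihood Score (CLS) test for tumor-pair clonality.

Given a tumor pair with ``n`` total distinct high-confidence somatic
mutations of which ``X`` are shared, the CLS is ``100 * X / n``.  Under
independence the shared count is modeled as ``X ~ Binomial(n, p0)`` where
``p0`` is the background rate at which independent tumor pairs share called
mutations (driver-gene coincidence plus technical artifacts; 3–4% is the
calibrated operating point for exome pipelines).  Clonality is declared by
an exact one-sided binomial test: reject independence when ``X >= c`` with
``c`` the smallest integer whose upper-tail probability under the null is
at most ``alpha``.  Exact two-sided Clopper-Pearson intervals accompany the
score.

The module exposes both a functional surface (:func:`cls_score`,
:func:`binomial_upper_p`, :func:`clopper_pearson`, :func:`run_cls_test`)
and a model/results pair (:class:`ClonalityTest` / :class:`CLSResult`)
in the statsmodels idiom::

    result = ClonalityTest.from_counts(50, 62).fit()
    print(result.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import beta as _beta
from scipy.stats import binom as _binom

from ._format import format_ci, format_p_value, format_percent
from .exceptions import UndefinedScoreError, ValidationError
from .hc_filter import HCFilterParams, HCProfile, build_profile

__all__ = [
    "TestParams",
    "CLSResult",
    "ClonalityTest",
    "cls_score",
    "binomial_upper_p",
    "clopper_pearson",
    "run_cls_test",
]


@dataclass(frozen=True)
class TestParams:
    """Operating parameters of the CLS test.

    p0
        Null shared-call rate among independent pairs (fraction).
    alpha
        One-sided significance level.
    pa
        Design alternative — the lowest shared-mutation rate expected in a
        clonal pair; used only to flag underpowered inputs.
    confidence
        Two-sided Clopper-Pearson confidence level.
    """

    p0: float = 0.04
    alpha: float = 0.05
    pa: float = 0.15
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.p0 < 1.0:
            raise ValidationError(f"p0 must lie in (0, 1), got {self.p0}")
        if not self.p0 < self.pa < 1.0:
            raise ValidationError(f"need p0 < pa < 1, got p0={self.p0}, pa={self.pa}")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 < self.confidence < 1.0:
            raise ValidationError("confidence must lie in (0, 1)")


def cls_score(X: int, n: int) -> float:
    """Clonal Likelihood Score: 100 * X / n, unrounded.

    Raises :class:`UndefinedScoreError` when ``n == 0`` — with no HC
    mutations there is no test; report "no-test" instead.
    """
    if n == 0:
        raise UndefinedScoreError(
            "CLS undefined with zero total HC mutations; report no-test"
        )
    if not 0 <= X <= n:
        raise ValidationError(f"need 0 <= X <= n, got X={X}, n={n}")
    return 100.0 * X / n


def binomial_upper_p(X: int, n: int, p0: float) -> float:
    """Exact upper-tail probability P(B >= X) for B ~ Binomial(n, p0).

    Computed through the regularized incomplete beta function
    (``scipy.stats.binom.sf``), numerically exact far into the tails.
    """
    if not 0.0 < p0 < 1.0:
        raise ValidationError(f"p0 must lie in (0, 1), got {p0}")
    if not 0 <= X <= n:
        raise ValidationError(f"need 0 <= X <= n, got X={X}, n={n}")
    if X == 0:
        return 1.0
    return float(_binom.sf(X - 1, n, p0))


def clopper_pearson(X: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact two-sided Clopper-Pearson interval for a binomial proportion.

    Returns ``(low, high)`` as fractions.  The bounds are the standard beta
    quantiles: low is 0 when ``X == 0`` and high is 1 when ``X == n``.
    """
    if n < 1 or not 0 <= X <= n:
        raise ValidationError(f"need n >= 1 and 0 <= X <= n, got X={X}, n={n}")
    half = (1.0 - confidence) / 2.0
    low = 0.0 if X == 0 else float(_beta.ppf(half, X, n - X + 1))
    high = 1.0 if X == n else float(_beta.ppf(1.0 - half, X + 1, n - X))
    return low, high


@dataclass(frozen=True)
class CLSResult:
    """Results of the CLS test (the fitted-results object).

    All numeric fields are unrounded; ``summary()`` and ``to_dict()`` apply
    the display conventions (integer percent at >= 2%, one decimal below;
    p-values clipped to "<1e-15").
    """

    X: int
    n: int
    cls: float
    p_value: float
    ci_low: float
    ci_high: float
    decision: str
    underpowered: bool
    critical_value: int
    n_required: int
    params: TestParams
    filter_params: HCFilterParams | None = None

    @property
    def cls_display(self) -> str:
        return format_percent(self.cls)

    @property
    def ci_display(self) -> str:
        return format_ci(self.ci_low, self.ci_high)

    def to_dict(self) -> dict:
        d = {
            "X": self.X,
            "n": self.n,
            "cls": self.cls,
            "cls_display": self.cls_display,
            "p_value": self.p_value,
            "p_value_display": format_p_value(self.p_value),
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_display": self.ci_display,
            "decision": self.decision,
            "underpowered": self.underpowered,
            "critical_value": self.critical_value,
            "n_required": self.n_required,
            "params": {
                "p0": self.params.p0,
                "alpha": self.params.alpha,
                "pa": self.params.pa,
                "confidence": self.params.confidence,
            },
        }
        if self.filter_params is not None:
            d["filter_params"] = {
                "germline_min_hq_depth": self.filter_params.germline_min_hq_depth,
                "germline_hq_quality_threshold": self.filter_params.germline_hq_quality_threshold,
                "germline_max_alt_reads": self.filter_params.germline_max_alt_reads,
                "germline_max_alt_fraction": self.filter_params.germline_max_alt_fraction,
                "tumor_min_depth": self.filter_params.tumor_min_depth,
                "exclude_dbsnp": self.filter_params.exclude_dbsnp,
            }
        return d

    def summary(self) -> str:
        """Human-readable summary table."""
        pct = int(round(100 * self.params.confidence))
        lines = [
            "Clonal Likelihood Score test",
            "=" * 44,
            f"shared HC mutations (X)      {self.X}",
            f"total HC mutations (n)       {self.n}",
            f"CLS                          {self.cls_display}%",
            f"{pct}% Clopper-Pearson CI      {self.ci_display}",
            f"one-sided p-value (p0={self.params.p0:g})  {format_p_value(self.p_value)}",
            f"critical value c             {self.critical_value}",
            f"decision                     {self.decision}",
        ]
        if self.underpowered:
            lines.append(
                f"note: n={self.n} < {self.n_required} required for 80% power "
                f"at pa={self.params.pa:g}"
            )
        lines.append("=" * 44)
        return "\n".join(lines)


class ClonalityTest:
    """Model object: the exact binomial clonality test for one tumor pair.

    Construct from raw counts, an HC profile, or a mutation table, then call
    :meth:`fit` to obtain a :class:`CLSResult`.
    """

    def __init__(self, profile: HCProfile, params: TestParams = TestParams()):
        self.profile = profile
        self.params = params

    @classmethod
    def from_counts(cls, X: int, n: int, params: TestParams = TestParams()) -> "ClonalityTest":
        return cls(HCProfile.from_counts(X, n), params)

    @classmethod
    def from_profile(cls, profile: HCProfile, params: TestParams = TestParams()) -> "ClonalityTest":
        return cls(profile, params)

    @classmethod
    def from_mutation_table(
        cls,
        path,
        params: TestParams = TestParams(),
        filter_params: HCFilterParams = HCFilterParams(),
    ) -> "ClonalityTest":
        """Read a canonical mutation table and apply the HC filter."""
        from .variant_io import read_mutation_table

        model = cls(build_profile(read_mutation_table(path), filter_params), params)
        model._filter_params = filter_params
        return model

    _filter_params: HCFilterParams | None = None

    def fit(self) -> CLSResult:
        """Run the exact test and return the results object."""
        from .study_design import critical_value, min_n_for_power

        X, n = self.profile.X, self.profile.n
        p = self.params
        if n == 0:
            raise UndefinedScoreError(
                "no HC mutations survive filtering (n = 0); the CLS test "
                "cannot be run — report no-test"
            )
        score = cls_score(X, n)
        p_value = binomial_upper_p(X, n, p.p0)
        lo, hi = clopper_pearson(X, n, p.confidence)
        c = critical_value(n, p.p0, p.alpha)
        n_req = min_n_for_power(p.p0, p.pa, p.alpha, 0.80).n_required
        underpowered = n < n_req
        if X >= c:
            decision = "clonal"
        elif underpowered:
            decision = "underpowered"
        else:
            decision = "independence_not_rejected"
        return CLSResult(
            X=X,
            n=n,
            cls=score,
            p_value=p_value,
            ci_low=100.0 * lo,
            ci_high=100.0 * hi,
            decision=decision,
            underpowered=underpowered,
            critical_value=c,
            n_required=n_req,
            params=p,
            filter_params=self._filter_params,
        )


def run_cls_test(profile: HCProfile, params: TestParams = TestParams()) -> CLSResult:
    """Functional wrapper: fit :class:`ClonalityTest` on an HC profile."""
    return ClonalityTest(profile, params).fit()
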