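"""Bayesian estimation of dispensable interactome content.

Model
-----
A new missense mutation is effectively neutral (N), mildly deleterious (M)
or strongly detrimental (S) with prior probabilities P(N), P(M), P(S)
(defaults 0.27 / 0.53 / 0.20, from population-genetic estimates of the
fitness-effect distribution of human missense mutations).  Common mutations
from healthy individuals proxy class N, Mendelian disease mutations proxy
class M, and class S mutations are assumed quasi-null rather than edgetic,
so P(E|S) = 0.  Given edgetic rates P(E|N) = k_N/n_N and P(E|M) = k_M/n_M
measured on a structural interactome, the fraction of the interactome that
is dispensable — effectively neutral upon disruption — is obtained by Bayes'
theorem:

    P(E)   = P(E|N) P(N) + P(E|M) P(M) + P(E|S) P(S)
    P(N|E) = P(E|N) P(N) / P(E)

Because P(N) and P(M) are constants, P(N|E) depends on the data only
through the rate ratio r = P(E|M)/P(E|N):

    1 / P(N|E) = r * P(M)/P(N) + 1

The 95% confidence interval for r uses the log-scale (Katz) interval for a
ratio of two binomial proportions,

    log r  +/-  z * sqrt(1/k_M - 1/n_M + 1/k_N - 1/n_N),

and each bound is mapped through the identity above; the ratio's lower
bound yields the upper bound on P(N|E).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from .edgotypes import EdgeticCounts, EdgotypeCall, tally_counts

__all__ = [
    "FitnessPriors",
    "DEFAULT_PRIORS",
    "DispensabilityEstimate",
    "DispensabilityModel",
    "DispensabilityResults",
    "PUBLISHED_COUNTS",
    "p_edgetic",
    "p_dispensable",
    "ci95_dispensable",
    "estimate",
]

VARIANTS = ("standard", "mono_edgetic", "quasi_null_as_edgetic")


@dataclass(frozen=True)
class FitnessPriors:
    """Prior fitness-class probabilities for a new missense mutation."""

    p_N: float = 0.27
    p_M: float = 0.53
    p_S: float = 0.20

    def __post_init__(self) -> None:
        for name in ("p_N", "p_M", "p_S"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.p_N + self.p_M + self.p_S - 1.0) > 1e-9:
            raise ValueError("fitness-class priors must sum to 1")


DEFAULT_PRIORS = FitnessPriors()

#: Edgetic tallies published for the two structural interactomes (geometry-
#: and physics-based calls) and for the experimental edgotyping screen;
#: (k_N, n_N, k_M, n_M) — edgetic / total, non-disease then disease.
PUBLISHED_COUNTS: dict[str, EdgeticCounts] = {
    "y2h_geometry": EdgeticCounts(19, 376, 27, 145),
    "intact_geometry": EdgeticCounts(164, 2394, 140, 908),
    "experiment": EdgeticCounts(2, 47, 62, 197),
    "y2h_physics": EdgeticCounts(12, 374, 16, 140),
    "intact_physics": EdgeticCounts(103, 2360, 104, 894),
}


def p_edgetic(
    counts: EdgeticCounts,
    priors: FitnessPriors = DEFAULT_PRIORS,
    p_E_given_S: float = 0.0,
) -> float:
    """Marginal probability that a new missense mutation is edgetic."""
    return (
        counts.rate_N * priors.p_N
        + counts.rate_M * priors.p_M
        + p_E_given_S * priors.p_S
    )


def p_dispensable(
    counts: EdgeticCounts,
    priors: FitnessPriors = DEFAULT_PRIORS,
    p_E_given_S: float = 0.0,
) -> float:
    """Posterior probability that an edgetic mutation is neutral, P(N|E) —
    the dispensable fraction of the interactome.  Exact count fractions are
    used throughout; rounding happens only at reporting."""
    pe = p_edgetic(counts, priors, p_E_given_S)
    if pe == 0.0:
        raise ZeroDivisionError("P(E) = 0: dispensable fraction undefined")
    if counts.k_N == 0:
        import warnings

        warnings.warn("k_N = 0: P(N|E) estimate is 0", stacklevel=2)
    return counts.rate_N * priors.p_N / pe


def ci95_dispensable(
    counts: EdgeticCounts,
    priors: FitnessPriors = DEFAULT_PRIORS,
    z: float = 1.96,
    continuity_correction: bool = False,
) -> tuple[float, float]:
    """95% confidence interval on P(N|E) via the Katz log interval on the
    rate ratio r = P(E|M)/P(E|N).

    A zero numerator on either side makes the log interval undefined; pass
    ``continuity_correction=True`` to add 0.5 to every cell (Haldane style).
    """
    k_N, n_N, k_M, n_M = counts.k_N, counts.n_N, counts.k_M, counts.n_M
    if (k_N < 1 or k_M < 1) and not continuity_correction:
        raise ValueError(
            "zero edgetic count: the log-ratio CI is undefined; "
            "retry with continuity_correction=True"
        )
    if continuity_correction:
        k_N, n_N, k_M, n_M = k_N + 0.5, n_N + 0.5, k_M + 0.5, n_M + 0.5
    r = (k_M / n_M) / (k_N / n_N)
    se = math.sqrt(1.0 / k_M - 1.0 / n_M + 1.0 / k_N - 1.0 / n_N)
    r_lo = math.exp(math.log(r) - z * se)
    r_hi = math.exp(math.log(r) + z * se)
    ratio_m_over_n = priors.p_M / priors.p_N
    # smaller ratio -> larger dispensable fraction
    hi = 1.0 / (r_lo * ratio_m_over_n + 1.0)
    lo = 1.0 / (r_hi * ratio_m_over_n + 1.0)
    return (lo, hi)


@dataclass(frozen=True)
class DispensabilityEstimate:
    p_edgetic: float
    p_dispensable: float
    ci95: tuple[float, float]
    counts: EdgeticCounts
    priors: FitnessPriors
    variant: str = "standard"

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("confidence bounds must be ordered within [0, 1]")


def estimate(
    counts: EdgeticCounts,
    priors: FitnessPriors = DEFAULT_PRIORS,
    variant: str = "standard",
    z: float = 1.96,
    p_E_given_S: float = 0.0,
    continuity_correction: bool = False,
) -> DispensabilityEstimate:
    """Bundle P(E), P(N|E) and the 95% CI for one set of edgetic counts.

    ``variant`` records how the counts were tallied: "standard" (edgetic =
    at least one disrupted PPI), "mono_edgetic" (numerators count mutations
    disrupting exactly one PPI) or "quasi_null_as_edgetic" (numerators
    include quasi-null calls from experimental-style inputs).  The arithmetic
    is identical across variants; the tag documents provenance of the counts.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    return DispensabilityEstimate(
        p_edgetic=p_edgetic(counts, priors, p_E_given_S),
        p_dispensable=p_dispensable(counts, priors, p_E_given_S),
        ci95=ci95_dispensable(counts, priors, z, continuity_correction),
        counts=counts,
        priors=priors,
        variant=variant,
    )


class DispensabilityModel:
    """Dispensable-content model for one set of edgetic counts.

    Parameters
    ----------
    counts
        Edgetic tallies (k_N, n_N, k_M, n_M).
    priors
        Fitness-class priors; default 0.27 / 0.53 / 0.20.
    variant
        Tally convention the counts follow (see :func:`estimate`).

    Examples
    --------
    >>> model = DispensabilityModel(EdgeticCounts(19, 376, 27, 145))
    >>> res = model.fit()
    >>> round(res.p_dispensable * 100, 1)
    12.1
    """

    def __init__(
        self,
        counts: EdgeticCounts,
        priors: FitnessPriors = DEFAULT_PRIORS,
        variant: str = "standard",
    ) -> None:
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        self.counts = counts
        self.priors = priors
        self.variant = variant

    @classmethod
    def from_calls(
        cls,
        calls: list[EdgotypeCall],
        priors: FitnessPriors = DEFAULT_PRIORS,
        variant: str = "standard",
    ) -> "DispensabilityModel":
        """Build the model from per-mutation edgotype calls."""
        counts = tally_counts(calls, mono_only=(variant == "mono_edgetic"))
        return cls(counts, priors, variant)

    def fit(
        self,
        z: float = 1.96,
        p_E_given_S: float = 0.0,
        continuity_correction: bool = False,
    ) -> "DispensabilityResults":
        est = estimate(
            self.counts, self.priors, self.variant, z, p_E_given_S, continuity_correction
        )
        return DispensabilityResults(self, est, z)


class DispensabilityResults:
    """Fitted dispensable-content estimates with their confidence interval."""

    def __init__(
        self, model: DispensabilityModel, est: DispensabilityEstimate, z: float
    ) -> None:
        self.model = model
        self.estimate = est
        self.z = z

    @property
    def p_edgetic(self) -> float:
        return self.estimate.p_edgetic

    @property
    def p_dispensable(self) -> float:
        return self.estimate.p_dispensable

    @property
    def ci95(self) -> tuple[float, float]:
        return self.estimate.ci95

    def conf_int(self) -> tuple[float, float]:
        return self.estimate.ci95

    def to_dict(self) -> dict:
        c, p = self.model.counts, self.model.priors
        lo, hi = self.ci95
        return {
            "variant": self.model.variant,
            "counts": {"k_N": c.k_N, "n_N": c.n_N, "k_M": c.k_M, "n_M": c.n_M},
            "priors": {"p_N": p.p_N, "p_M": p.p_M, "p_S": p.p_S},
            "p_edgetic": self.p_edgetic,
            "p_dispensable": self.p_dispensable,
            "ci95": [lo, hi],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        c, p = self.model.counts, self.model.priors
        lo, hi = self.ci95
        lines = [
            "Dispensable PPI content estimate",
            "=" * 48,
            f"variant:               {self.model.variant}",
            f"edgetic non-disease:   {c.k_N} / {c.n_N}  (P(E|N) = {c.rate_N:.4f})",
            f"edgetic disease:       {c.k_M} / {c.n_M}  (P(E|M) = {c.rate_M:.4f})",
            f"priors P(N)/P(M)/P(S): {p.p_N:.2f} / {p.p_M:.2f} / {p.p_S:.2f}",
            "-" * 48,
            f"P(E)    = {self.p_edgetic * 100:5.1f} %",
            f"P(N|E)  = {self.p_dispensable * 100:5.1f} %",
            f"95% CI  = {lo * 100:5.1f} - {hi * 100:4.1f} %   (z = {self.z})",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        lo, hi = self.ci95
        return (
            f"<DispensabilityResults P(N|E)={self.p_dispensable:.3f} "
            f"CI=({lo:.3f}, {hi:.3f})>"
        )
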