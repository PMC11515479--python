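"""Agreement between estimate streams and blood-gas references.

Differences are always estimate minus reference PaCO2.  Summary metrics
are the mean difference, mean absolute error (MAE), sample standard
deviation of the differences (SD, n-1 denominator) and the standard
error SE = SD/sqrt(n).  Because the differences are not normally
distributed, Bland-Altman limits of agreement are the empirical 2.5th and
97.5th percentiles of the differences (linear interpolation between order
statistics) rather than mean +- 1.96 SD.  Reported values are rounded to
two decimals at serialisation only; internal comparisons keep full
precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import (ConsistencyError, DomainError, InsufficientDataError,
                     InvalidConfigError)
from .estimator import METHOD_ETCO2, METHOD_RLR, EstimateRecord
from .preprocess import FilterConfig
from .records import BloodGasRecord


@dataclass
class AgreementReport:
    """Agreement summary of one estimation method against blood gases."""

    method: str
    n: int
    mean_diff: float
    mae: float
    sd: float
    se: float
    loa_low: float
    loa_high: float

    def rounded(self, ndigits: int = 2) -> dict:
        """Two-decimal presentation used in result tables."""
        return {
            "method": self.method, "n": self.n,
            "mean_diff": round(self.mean_diff, ndigits),
            "mae": round(self.mae, ndigits),
            "sd": round(self.sd, ndigits),
            "se": round(self.se, ndigits),
            "loa_low": round(self.loa_low, ndigits),
            "loa_high": round(self.loa_high, ndigits),
        }


@dataclass
class MethodComparison:
    """Per-method agreement on an identical blood-gas set, plus the MAE
    reduction of the model estimate relative to unaltered etCO2."""

    reports: dict[str, AgreementReport]
    mae_reduction_abs: float | None
    mae_reduction_rel: float | None
    n_bgas_used: int
    n_bgas_dropped: int


def pair_estimates(estimates: Sequence[EstimateRecord],
                   bgas: Sequence[BloodGasRecord]
                   ) -> tuple[list[tuple[float, float]], list[BloodGasRecord]]:
    """Pair each blood gas with the latest non-withheld estimate inside
    its documented minute ``[m, m + 60)``.

    Returns the (estimate, PaCO2) pairs and the blood gases that had no
    usable estimate in their minute.
    """
    times = np.array([e.time for e in estimates])
    order = np.argsort(times, kind="stable")
    pairs: list[tuple[float, float]] = []
    dropped: list[BloodGasRecord] = []
    for bga in bgas:
        m = bga.documented_minute_s
        lo = np.searchsorted(times[order], m, side="left")
        hi = np.searchsorted(times[order], m + 60.0, side="left")
        chosen = None
        for k in range(hi - 1, lo - 1, -1):
            e = estimates[order[k]]
            if not e.withheld:
                chosen = e
                break
        if chosen is None:
            dropped.append(bga)
        else:
            pairs.append((float(chosen.value), float(bga.paco2)))
    return pairs, dropped


def _differences(pairs: Sequence[tuple[float, float]]) -> np.ndarray:
    if len(pairs) < 2:
        raise InsufficientDataError("need at least 2 pairs")
    arr = np.asarray(pairs, dtype=float)
    return arr[:, 0] - arr[:, 1]


def error_metrics(pairs: Sequence[tuple[float, float]]
                  ) -> tuple[int, float, float, float, float]:
    """``(n, mean_diff, mae, sd, se)`` of estimate-minus-reference."""
    d = _differences(pairs)
    n = d.size
    sd = float(np.std(d, ddof=1))
    return (n, float(np.mean(d)), float(np.mean(np.abs(d))), sd,
            sd / np.sqrt(n))


def bland_altman(pairs: Sequence[tuple[float, float]],
                 method: str = "rlr",
                 q_low: float = 0.025, q_high: float = 0.975
                 ) -> AgreementReport:
    """Agreement report with quantile limits of agreement.

    The limits are the empirical ``q_low``/``q_high`` quantiles of the
    differences, computed by linear interpolation between order
    statistics (position ``h = (n - 1) q + 1``).
    """
    if not 0 <= q_low < q_high <= 1:
        raise InvalidConfigError("quantile orders must satisfy 0 <= q_low < q_high <= 1")
    d = _differences(pairs)
    n, mean_diff, mae, sd, se = error_metrics(pairs)
    loa_low, loa_high = np.quantile(d, [q_low, q_high])
    return AgreementReport(method=method, n=n, mean_diff=mean_diff, mae=mae,
                           sd=sd, se=se, loa_low=float(loa_low),
                           loa_high=float(loa_high))


def bland_altman_points(pairs: Sequence[tuple[float, float]]
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Plot coordinates: mean of the two methods vs their difference."""
    arr = np.asarray(pairs, dtype=float)
    return arr.mean(axis=1), arr[:, 0] - arr[:, 1]


def design_phase_pairs(samples, model) -> list[tuple[float, float]]:
    """(prediction, PaCO2) pairs from model evaluation on averaged samples.

    This is the design-population scoring route: the model is evaluated on
    the same centred-window averages the regression used, against each
    sample's reference PaCO2.  Samples whose covariates are missing are
    skipped.
    """
    from .estimator import predict

    pairs = []
    for s in samples:
        if s.paco2 is None:
            continue
        value = predict(model, s)
        if value is not None:
            pairs.append((value, float(s.paco2)))
    return pairs


def bland_altman_plot(pairs: Sequence[tuple[float, float]], path,
                      method: str = "rlr",
                      q_low: float = 0.025, q_high: float = 0.975) -> None:
    """Render a Bland-Altman plot (SVG/PNG by file extension).

    Requires matplotlib (optional dependency).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    report = bland_altman(pairs, method=method, q_low=q_low, q_high=q_high)
    means, diffs = bland_altman_points(pairs)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=12, alpha=0.6)
    ax.axhline(report.mean_diff, color="k", lw=1, label="mean difference")
    for loa in (report.loa_low, report.loa_high):
        ax.axhline(loa, color="k", lw=1, ls="--")
    ax.set_xlabel("mean of estimate and PaCO2 [mmHg]")
    ax.set_ylabel("estimate - PaCO2 [mmHg]")
    ax.set_title(f"{method}: quantile limits of agreement "
                 f"[{report.loa_low:.2f}, {report.loa_high:.2f}] mmHg")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def relative_reduction(mae_ref: float, mae_new: float
                       ) -> tuple[float, float]:
    """Absolute (mmHg) and relative (%, two decimals) MAE reduction."""
    if mae_ref <= 0:
        raise DomainError("reference MAE must be positive")
    abs_red = mae_ref - mae_new
    return abs_red, round(100.0 * abs_red / mae_ref, 2)


def compare_methods(streams: Mapping[str, Sequence[EstimateRecord]],
                    bgas: Sequence[BloodGasRecord],
                    filter_cfg: FilterConfig = FilterConfig(),
                    include_high_paco2: bool = False,
                    q_low: float = 0.025, q_high: float = 0.975
                    ) -> MethodComparison:
    """Score several estimate streams against one blood-gas reference set.

    A blood gas enters the comparison iff its PaCO2 passes the validity
    cut (PaCO2 <= ``filter_cfg.paco2_max`` unless ``include_high_paco2``)
    and *every* method has a non-withheld estimate inside its documented
    minute, so all reports share the identical reference set.  (The low
    tidal-volume rule acts through the streams' own withholding.)  The MAE
    reduction compares the model estimate against unaltered etCO2 when
    both streams are present.
    """
    if not streams:
        raise ConsistencyError("at least one estimate stream is required")
    eligible = [b for b in bgas
                if include_high_paco2 or b.paco2 <= filter_cfg.paco2_max]
    per_method_pairs: dict[str, dict[float, tuple[float, float]]] = {}
    usable_keys: set[float] | None = None
    for name, stream in streams.items():
        pairs, dropped = pair_estimates(stream, eligible)
        dropped_keys = {b.documented_minute_s for b in dropped}
        keyed = {}
        i = 0
        for b in eligible:
            if b.documented_minute_s in dropped_keys:
                continue
            keyed[b.documented_minute_s] = pairs[i]
            i += 1
        per_method_pairs[name] = keyed
        keys = set(keyed)
        usable_keys = keys if usable_keys is None else usable_keys & keys
    assert usable_keys is not None
    kept_keys = sorted(usable_keys)
    if len(kept_keys) < 2:
        raise InsufficientDataError("fewer than 2 blood gases usable by all methods")
    reports = {
        name: bland_altman([keyed[k] for k in kept_keys], method=name,
                           q_low=q_low, q_high=q_high)
        for name, keyed in sorted(per_method_pairs.items())
    }
    abs_red = rel_red = None
    if METHOD_RLR in reports and METHOD_ETCO2 in reports:
        abs_red, rel_red = relative_reduction(reports[METHOD_ETCO2].mae,
                                              reports[METHOD_RLR].mae)
    return MethodComparison(reports=reports, mae_reduction_abs=abs_red,
                            mae_reduction_rel=rel_red,
                            n_bgas_used=len(kept_keys),
                            n_bgas_dropped=len(eligible) - len(kept_keys))


def evaluate_population(
        per_animal: Sequence[tuple[Mapping[str, Sequence[EstimateRecord]],
                                   Sequence[BloodGasRecord]]],
        filter_cfg: FilterConfig = FilterConfig(),
        include_high_paco2: bool = False,
        q_low: float = 0.025, q_high: float = 0.975) -> MethodComparison:
    """Pool per-animal streams into one population-level comparison.

    Pairs are keyed by (animal, documented minute); a blood gas enters the
    pooled reference set only if every method pairs it, exactly as in
    :func:`compare_methods`.
    """
    method_names: set[str] | None = None
    pooled: dict[str, dict[tuple[str, float], tuple[float, float]]] = {}
    n_eligible = 0
    for streams, bgas in per_animal:
        names = set(streams)
        if method_names is None:
            method_names = names
            pooled = {name: {} for name in names}
        elif names != method_names:
            raise ConsistencyError("all animals must provide the same methods")
        eligible = [b for b in bgas
                    if include_high_paco2 or b.paco2 <= filter_cfg.paco2_max]
        n_eligible += len(eligible)
        for name, stream in streams.items():
            pairs, dropped = pair_estimates(stream, eligible)
            dropped_keys = {b.documented_minute_s for b in dropped}
            i = 0
            for b in eligible:
                if b.documented_minute_s in dropped_keys:
                    continue
                pooled[name][(b.animal_id, b.documented_minute_s)] = pairs[i]
                i += 1
    if method_names is None:
        raise ConsistencyError("no animals supplied")
    usable = set.intersection(*(set(keyed) for keyed in pooled.values()))
    kept_keys = sorted(usable)
    if len(kept_keys) < 2:
        raise InsufficientDataError("fewer than 2 blood gases usable by all methods")
    reports = {
        name: bland_altman([keyed[k] for k in kept_keys], method=name,
                           q_low=q_low, q_high=q_high)
        for name, keyed in sorted(pooled.items())
    }
    abs_red = rel_red = None
    if METHOD_RLR in reports and METHOD_ETCO2 in reports:
        abs_red, rel_red = relative_reduction(reports[METHOD_ETCO2].mae,
                                              reports[METHOD_RLR].mae)
    return MethodComparison(reports=reports, mae_reduction_abs=abs_red,
                            mae_reduction_rel=rel_red,
                            n_bgas_used=len(kept_keys),
                            n_bgas_dropped=n_eligible - len(kept_keys))
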