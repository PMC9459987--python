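"""Monte-Carlo factorial study of MNF/MDF estimation error.

The experiment crosses three factors — estimation *method* (Welch plus six
Burg orders), signal *duration* (250–2000 ms) and *SNR* (5–20 dB) — with C
seeded realizations per cell.  For every realization each method estimates
the PSD, MNF and MDF are extracted, and the absolute error against the
analytic reference of the ideal spectrum is recorded.  Accuracy is
summarized per cell as the mean absolute error (MAE) and its standard
deviation; the factor structure is analyzed with a factorial ANOVA cascade
(three-way, then two-way per SNR, then one-way on method per duration) with
Tukey HSD post-hoc comparisons wherever the method effect is significant.

Seeding is hierarchical: a master seed spawns per-(duration, SNR,
realization) substreams, one for the shaped-noise driver and one for the
measurement noise, so any cell is reproducible in isolation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .psd_estimation import PsdEstimate, WelchConfig, burg_fit, burg_psd, welch_psd
from .signal_model import (
    IdealSpectrum,
    ShapingFilter,
    add_noise,
    design_shaping_filter,
    generate_clean,
    n_samples_for,
)
from .spectral_features import ideal_reference, mean_frequency, median_frequency

__all__ = [
    "DEFAULT_METHODS",
    "StudyConfig",
    "StudyTable",
    "AnovaResult",
    "CascadeResult",
    "estimate_psd",
    "run_grid",
    "mae_summary",
    "factorial_anova",
    "tukey_hsd",
    "anova_cascade",
]

#: the seven estimation methods compared by the study
DEFAULT_METHODS = ("welch", "burg3", "burg4", "burg7", "burg10", "burg15", "burg30")


@dataclass(frozen=True)
class StudyConfig:
    """Factor levels and scale of the Monte-Carlo experiment.

    Defaults reproduce the full study design: 8 durations (250–2000 ms in
    250 ms steps), SNR in {5, 10, 15, 20} dB, the seven methods, and 1000
    realizations per cell.  ``realizations`` can be reduced for desk-scale
    runs without touching the factor structure.
    """

    durations_ms: tuple = tuple(range(250, 2001, 250))
    snr_db: tuple = (5.0, 10.0, 15.0, 20.0)
    methods: tuple = DEFAULT_METHODS
    realizations: int = 1000
    master_seed: int = 0
    spectrum: IdealSpectrum = field(default_factory=IdealSpectrum)
    welch: WelchConfig = field(default_factory=WelchConfig)

    def __post_init__(self) -> None:
        if self.realizations < 2:
            raise ValueError("need at least 2 realizations per cell")
        if not self.methods:
            raise ValueError("method list is empty")
        if any(t <= 0 for t in self.durations_ms):
            raise ValueError("durations must be positive")


@dataclass
class StudyTable:
    """Long-format realization table plus provenance.

    ``frame`` has one row per (method, duration, SNR, realization) with the
    feature estimates, their signed errors and absolute errors against the
    ideal reference.  ``flagged_cells`` lists cells where more than 1% of
    realizations failed estimation.
    """

    frame: pd.DataFrame
    config: StudyConfig
    reference_mnf: float
    reference_mdf: float
    flagged_cells: list = field(default_factory=list)


def _parse_method(method: str) -> int | None:
    """Burg order for 'burg<p>' tags, None for 'welch'."""
    if method == "welch":
        return None
    if method.startswith("burg"):
        order = int(method[4:])
        if order < 1:
            raise ValueError(f"invalid Burg order in {method!r}")
        return order
    raise ValueError(f"unknown method {method!r}")


def estimate_psd(
    x: np.ndarray,
    f_s: float,
    method: str,
    welch_config: WelchConfig | None = None,
) -> PsdEstimate:
    """Dispatch one signal to the named estimator on the length-N grid."""
    order = _parse_method(method)
    if order is None:
        return welch_psd(x, f_s, config=welch_config)
    model = burg_fit(x, order)
    return burg_psd(model, f_s, nfft=len(x))


def _realization_seeds(master_seed: int, d_idx: int, s_idx: int, c: int):
    """Independent (signal, noise) seed pair for one realization."""
    sig = np.random.SeedSequence(entropy=master_seed, spawn_key=(d_idx, s_idx, c, 0))
    noi = np.random.SeedSequence(entropy=master_seed, spawn_key=(d_idx, s_idx, c, 1))
    return int(sig.generate_state(1)[0]), int(noi.generate_state(1)[0])


def run_grid(config: StudyConfig) -> StudyTable:
    """Run the full factorial Monte-Carlo experiment.

    Deterministic given ``config.master_seed``; per-realization estimator
    failures are recorded as missing rows rather than aborting, and any
    cell losing more than 1% of its realizations is flagged.
    """
    ref = ideal_reference(
        f_l=config.spectrum.f_l, f_h=config.spectrum.f_h, f_s=config.spectrum.f_s
    )
    filters: dict[int, ShapingFilter] = {}
    rows: list[dict] = []
    flagged: list[tuple] = []
    for d_idx, duration in enumerate(config.durations_ms):
        n = n_samples_for(duration, config.spectrum.f_s)
        length = min(max(n, 64), 512)
        if length not in filters:
            filters[length] = design_shaping_filter(config.spectrum, length=length)
        shaping = filters[length]
        for s_idx, snr in enumerate(config.snr_db):
            failures = 0
            for c in range(config.realizations):
                seed_sig, seed_noi = _realization_seeds(
                    config.master_seed, d_idx, s_idx, c
                )
                clean = generate_clean(
                    duration,
                    config.spectrum,
                    seed_sig,
                    shaping=shaping,
                    realization_index=c,
                )
                noisy = add_noise(clean, snr, seed_noi)
                for method in config.methods:
                    try:
                        psd = estimate_psd(
                            noisy.samples,
                            config.spectrum.f_s,
                            method,
                            welch_config=config.welch,
                        )
                        mnf = mean_frequency(psd)
                        mdf = median_frequency(psd)
                    except ValueError:
                        failures += 1
                        continue
                    rows.append(
                        {
                            "method": method,
                            "duration_ms": duration,
                            "snr_db": snr,
                            "realization": c,
                            "mnf_hz": mnf,
                            "mdf_hz": mdf,
                            "err_mnf": abs(ref.mnf - mnf),
                            "err_mdf": abs(ref.mdf - mdf),
                            "bias_mnf": mnf - ref.mnf,
                            "bias_mdf": mdf - ref.mdf,
                        }
                    )
            if failures > 0.01 * config.realizations * len(config.methods):
                flagged.append((duration, snr, failures))
    frame = pd.DataFrame(rows)
    return StudyTable(
        frame=frame,
        config=config,
        reference_mnf=ref.mnf,
        reference_mdf=ref.mdf,
        flagged_cells=flagged,
    )


def _response_column(parameter: str) -> str:
    if parameter not in ("mnf", "mdf"):
        raise ValueError("parameter must be 'mnf' or 'mdf'")
    return f"err_{parameter}"


def mae_summary(table: StudyTable | pd.DataFrame, parameter: str) -> pd.DataFrame:
    """Per-cell mean absolute error, its SD, the signed bias, and n.

    One row per (method, duration_ms, snr_db).  Cells absent from the table
    (all realizations failed) are simply missing from the output.
    """
    frame = table.frame if isinstance(table, StudyTable) else table
    if frame.empty:
        raise ValueError("empty study table")
    col = _response_column(parameter)
    bias_col = col.replace("err", "bias")
    grouped = frame.groupby(["method", "duration_ms", "snr_db"], observed=True)
    out = grouped.agg(
        mae_hz=(col, "mean"),
        sd_hz=(col, "std"),
        bias_hz=(bias_col, "mean"),
        n=(col, "size"),
    ).reset_index()
    return out


@dataclass(frozen=True)
class AnovaResult:
    """Fixed-effects factorial ANOVA table for a balanced design."""

    table: pd.DataFrame  # index: source; columns: sum_sq, df, mean_sq, F, p
    factors: tuple
    n_obs: int

    def p(self, source: str) -> float:
        return float(self.table.loc[source, "p"])

    def significant(self, source: str, alpha: float = 0.05) -> bool:
        return self.p(source) < alpha


def _check_balanced(frame: pd.DataFrame, factors: list[str]) -> None:
    counts = frame.groupby(list(factors), observed=True).size()
    expected = int(np.prod([frame[f].nunique() for f in factors]))
    if len(counts) != expected or counts.nunique() != 1:
        raise ValueError(
            "unbalanced design: every factor-level combination must appear "
            "with the same number of realizations"
        )


def factorial_anova(
    table: StudyTable | pd.DataFrame,
    response: str,
    factors: list[str] | tuple,
) -> AnovaResult:
    """Full-factorial fixed-effects ANOVA (main effects + all interactions).

    Requires a balanced complete design (the study's is), which makes the
    sum-of-squares type irrelevant.  ``response`` is a column of the
    realization table, normally ``err_mnf`` or ``err_mdf`` (the analysis is
    run on per-realization absolute errors).
    """
    frame = table.frame if isinstance(table, StudyTable) else table
    factors = list(factors)
    _check_balanced(frame, factors)
    formula = f"{response} ~ " + "*".join(f"C({f})" for f in factors)
    fit = ols(formula, data=frame).fit()
    raw = anova_lm(fit, typ=1)
    raw = raw.rename(
        index=lambda s: s.replace("C(", "").replace(")", "").replace(":", " x ")
    )
    tab = pd.DataFrame(
        {
            "sum_sq": raw["sum_sq"],
            "df": raw["df"],
            "mean_sq": raw["sum_sq"] / raw["df"],
            "F": raw["F"],
            "p": raw["PR(>F)"],
        }
    )
    if np.var(frame[response].to_numpy()) == 0.0:
        # a constant response has no effects; 0/0 F ratios are meaningless
        tab.loc[tab.index != "Residual", ["F", "p"]] = np.nan
    tab.index.name = "source"
    return AnovaResult(table=tab, factors=tuple(factors), n_obs=len(frame))


def tukey_hsd(
    values: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All-pairs Tukey HSD comparisons with studentized-range adjusted p.

    Returns one row per pair with the mean difference, the adjusted
    p-value, and significance flags at the 0.05 / 0.01 / 0.001 levels.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("Tukey HSD needs at least two groups")
    if np.any(counts < 2):
        raise ValueError("every group needs at least two observations")
    res = pairwise_tukeyhsd(values, groups, alpha=alpha)
    frame = pd.DataFrame(
        res.summary().data[1:],
        columns=[str(c) for c in res.summary().data[0]],
    )
    out = pd.DataFrame(
        {
            "group1": frame["group1"],
            "group2": frame["group2"],
            "mean_diff": frame["meandiff"].astype(float),
            "p_adj": np.asarray(res.pvalues, dtype=float),
        }
    )
    out["sig_0.05"] = out["p_adj"] < 0.05
    out["sig_0.01"] = out["p_adj"] < 0.01
    out["sig_0.001"] = out["p_adj"] < 0.001
    return out


@dataclass
class CascadeResult:
    """Outcome of the nested ANOVA decision tree.

    ``three_way`` is always present.  If its three-way interaction is
    significant, ``two_way`` maps each SNR level to the (method, duration)
    ANOVA; where that interaction is significant, ``one_way`` holds a
    method-factor ANOVA per (snr, duration) slice, otherwise per
    (snr, None).  If the three-way interaction is not significant the
    single pooled one-way on method is stored under (None, None).
    ``posthoc`` maps the same keys to Tukey HSD tables wherever the method
    effect was significant.
    """

    response: str
    three_way: AnovaResult
    two_way: dict = field(default_factory=dict)
    one_way: dict = field(default_factory=dict)
    posthoc: dict = field(default_factory=dict)


def anova_cascade(
    table: StudyTable | pd.DataFrame,
    response: str,
    alpha: float = 0.05,
) -> CascadeResult:
    """Run the study's nested ANOVA decision tree on one error response."""
    frame = table.frame if isinstance(table, StudyTable) else table
    factors = ["method", "duration_ms", "snr_db"]
    result = CascadeResult(
        response=response,
        three_way=factorial_anova(frame, response, factors),
    )
    interaction3 = "method x duration_ms x snr_db"

    def _one_way(sub: pd.DataFrame, key: tuple) -> None:
        aov = factorial_anova(sub, response, ["method"])
        result.one_way[key] = aov
        if aov.significant("method", alpha):
            result.posthoc[key] = tukey_hsd(sub[response], sub["method"])

    if result.three_way.significant(interaction3, alpha):
        for snr in sorted(frame["snr_db"].unique()):
            sub = frame[frame["snr_db"] == snr]
            aov2 = factorial_anova(sub, response, ["method", "duration_ms"])
            result.two_way[snr] = aov2
            if aov2.significant("method x duration_ms", alpha):
                for dur in sorted(sub["duration_ms"].unique()):
                    _one_way(sub[sub["duration_ms"] == dur], (snr, dur))
            else:
                _one_way(sub, (snr, None))
    else:
        _one_way(frame, (None, None))
    return result
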