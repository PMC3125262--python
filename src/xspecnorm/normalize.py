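"""Control-probe normalization and centering for heterologous hybridization.

The core method: for each hybridized species, regress the natural log of
raw background-subtracted intensity of the *control* probes (features from
taxa universally diverged from every test species, so they report only
non-specific binding) on the nearest-neighbor duplex free energy ΔG37:

    ln(i_c) = alpha + beta * ΔG37(c) + e,      e ~ N(0, sigma²)

The fitted slope removes the thermodynamic component of non-specific
binding from every probe; the remaining location is pinned by a phase
shift equal to the median slope-adjusted control value, so that control
probes are centered on zero.  The adjusted intensity of probe p is then

    AI_p = ln(i_p) - beta * ΔG37(p) - shift,
    shift = median_c( ln(i_c) - beta * ΔG37(c) ).

AI ≈ 0 means non-specific baseline; AI > 0 suggests specific binding.
No assumption is made about the intensity distribution of target probes,
which is what makes the method appropriate for cross-species data.

Intensity data is carried in long-format DataFrames with columns
``probe_id``, ``chip_id``, ``intensity``; chip metadata maps ``chip_id``
to ``species`` and ``replicate``.  Natural log throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "CalibrationFit",
    "fit_control_model",
    "adjust_intensities",
    "combine_replicates",
    "normalize_experiment",
]


@dataclass(frozen=True)
class CalibrationFit:
    """Per-species calibration of non-specific binding vs ΔG37.

    ``alpha``/``beta`` are the OLS intercept and slope of ln(intensity)
    on ΔG37 over control probes; ``resid_sd`` the residual standard
    deviation; ``shift`` the median slope-adjusted control value used for
    centering; ``beta_se`` the standard error of the slope (NaN for the
    robust estimator).
    """

    species: str
    alpha: float
    beta: float
    resid_sd: float
    shift: float
    n_controls: int
    beta_se: float = float("nan")

    def beta_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided t confidence interval for the slope."""
        if not np.isfinite(self.beta_se):
            raise ValueError("slope standard error unavailable for this fit")
        tcrit = scipy.stats.t.ppf(0.5 + level / 2, df=self.n_controls - 2)
        return (self.beta - tcrit * self.beta_se, self.beta + tcrit * self.beta_se)


def _check_intensities(df: pd.DataFrame) -> None:
    bad = df.loc[~(df["intensity"] > 0)]
    if len(bad):
        raise ValueError(
            "non-positive intensity (cannot log-transform) for probe(s): "
            + ", ".join(map(str, bad["probe_id"].head(10)))
        )


def fit_control_model(
    controls: pd.DataFrame,
    dg: Mapping[str, float] | pd.Series,
    species: str = "",
    robust: bool = False,
) -> CalibrationFit:
    """OLS of ln(control intensity) on ΔG37 for one species.

    Parameters
    ----------
    controls
        Long-format intensities restricted to one species' control
        probes; columns ``probe_id``, ``intensity``.  If a probe appears
        on several chips its ln-intensities are averaged first (the
        per-species model carries no chip index).
    dg
        ΔG37 (kcal/mol) per probe id.
    robust
        Use the Theil–Sen slope with a median intercept instead of OLS.

    Returns a :class:`CalibrationFit`; the centering ``shift`` is the
    median over control probes of ``ln(i) - beta*dg``, so adjusted control
    intensities have median exactly zero.
    """
    _check_intensities(controls)
    dg = pd.Series(dg)
    missing = set(controls["probe_id"]) - set(dg.index)
    if missing:
        raise ValueError(
            "missing ΔG37 for control probe(s): "
            + ", ".join(map(str, sorted(missing)[:10]))
        )
    per_probe = (
        controls.assign(ln_i=np.log(controls["intensity"].to_numpy()))
        .groupby("probe_id", sort=False)["ln_i"]
        .mean()
    )
    x = dg.loc[per_probe.index].to_numpy(dtype=float)
    y = per_probe.to_numpy(dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError(
            f"degenerate design: need ≥3 distinct ΔG37 values, got {len(np.unique(x))}"
        )
    if robust:
        ts = scipy.stats.theilslopes(y, x)
        beta = float(ts.slope)
        alpha = float(np.median(y - beta * x))
        resid = y - alpha - beta * x
        resid_sd = float(np.std(resid, ddof=2)) if len(y) > 2 else 0.0
        beta_se = float("nan")
    else:
        res = sm.OLS(y, sm.add_constant(x)).fit()
        alpha, beta = (float(v) for v in res.params)
        resid_sd = float(np.sqrt(res.mse_resid)) if len(y) > 2 else 0.0
        beta_se = float(res.bse[1])
    shift = float(np.median(y - beta * x))
    return CalibrationFit(
        species=species,
        alpha=alpha,
        beta=beta,
        resid_sd=resid_sd,
        shift=shift,
        n_controls=len(y),
        beta_se=beta_se,
    )


def adjust_intensities(
    raw: pd.DataFrame,
    fit: CalibrationFit,
    dg: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """Adjusted intensity AI for every probe of one species.

    ``raw`` is long-format (``probe_id``, ``intensity``) for the species
    the fit came from; per-probe ln-intensities are averaged over chips.
    Returns columns ``probe_id``, ``species``, ``ai``.
    """
    _check_intensities(raw)
    dg = pd.Series(dg)
    missing = set(raw["probe_id"]) - set(dg.index)
    if missing:
        raise ValueError(
            "missing ΔG37 for probe(s): " + ", ".join(map(str, sorted(missing)[:10]))
        )
    per_probe = (
        raw.assign(ln_i=np.log(raw["intensity"].to_numpy()))
        .groupby("probe_id", sort=False)["ln_i"]
        .mean()
    )
    ai = per_probe.to_numpy() - fit.beta * dg.loc[per_probe.index].to_numpy() - fit.shift
    return pd.DataFrame(
        {"probe_id": per_probe.index, "species": fit.species, "ai": ai}
    ).reset_index(drop=True)


def combine_replicates(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-probe mean of per-chip adjusted intensities for one species.

    All tables must share the same probe universe and species label.
    """
    if not tables:
        raise ValueError("no tables to combine")
    universe = set(tables[0]["probe_id"])
    for t in tables[1:]:
        diff = universe.symmetric_difference(t["probe_id"])
        if diff:
            raise ValueError(
                f"probe universes differ between chips ({len(diff)} asymmetric probes)"
            )
    cat = pd.concat(tables, ignore_index=True)
    out = (
        cat.groupby(["probe_id", "species"], sort=False, as_index=False)["ai"].mean()
    )
    return out[["probe_id", "species", "ai"]]


def normalize_experiment(
    intensities: pd.DataFrame,
    chips: pd.DataFrame,
    probes: pd.DataFrame,
    dg: Mapping[str, float] | pd.Series,
    per_chip: bool = False,
    robust: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the calibration and adjustment for every species of a run.

    Parameters
    ----------
    intensities
        Long format ``probe_id``, ``chip_id``, ``intensity``.
    chips
        ``chip_id``, ``species``, ``replicate``.
    probes
        Probe annotation with at least ``probe_id`` and ``category``
        (``target``/``control``).
    per_chip
        Fit and adjust each chip separately, then average replicate AI
        values.  Default pools replicate chips on the ln scale per probe
        before the fit, since the model is indexed by species only.

    Returns
    -------
    (ai, fits)
        ``ai``: columns ``probe_id``, ``species``, ``ai`` (one row per
        probe per species).  ``fits``: one row per fit with the
        calibration parameters.
    """
    merged = intensities.merge(chips[["chip_id", "species"]], on="chip_id", how="left")
    if merged["species"].isna().any():
        orphans = merged.loc[merged["species"].isna(), "chip_id"].unique()
        raise ValueError(f"chips without species metadata: {list(orphans)[:10]}")
    control_ids = set(probes.loc[probes["category"] == "control", "probe_id"])
    ai_tables: list[pd.DataFrame] = []
    fit_rows: list[dict] = []
    for species, sp_df in merged.groupby("species", sort=True):
        if per_chip:
            per_chip_ai = []
            for chip_id, chip_df in sp_df.groupby("chip_id", sort=True):
                ctrl = chip_df[chip_df["probe_id"].isin(control_ids)]
                fit = fit_control_model(ctrl, dg, species=str(species), robust=robust)
                per_chip_ai.append(adjust_intensities(chip_df, fit, dg))
                fit_rows.append({"chip_id": chip_id, **_fit_row(fit)})
            ai_tables.append(combine_replicates(per_chip_ai))
        else:
            ctrl = sp_df[sp_df["probe_id"].isin(control_ids)]
            fit = fit_control_model(ctrl, dg, species=str(species), robust=robust)
            ai_tables.append(adjust_intensities(sp_df, fit, dg))
            fit_rows.append(_fit_row(fit))
    return pd.concat(ai_tables, ignore_index=True), pd.DataFrame(fit_rows)


def _fit_row(fit: CalibrationFit) -> dict:
    return {
        "species": fit.species,
        "alpha": fit.alpha,
        "beta": fit.beta,
        "resid_sd": fit.resid_sd,
        "shift": fit.shift,
        "n_controls": fit.n_controls,
        "beta_se": fit.beta_se,
    }
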