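"""Mitochondrial-state analytics.

Cells sorted by TMRE (a membrane-potential-dependent dye) signal fall into
quantile bins (HI/M1/M2/LO).  The HI bin is a mixture of slow- and
fast-growing high-potential cells plus a small low-potential impurity; an
exponential-growth bookkeeping model predicts how large the low-potential
fraction should become after regrowth if cells never switched from the high
to the low state.  Comparing that prediction with the observed fraction
quantifies state switching.  This module also scores respiration deficiency
from colony counts and estimates mtDNA copy number from qPCR standard
curves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SwitchingModelParams",
    "QpcrPlate",
    "QpcrResult",
    "quantile_bins",
    "predict_low_state_fraction",
    "second_day_prediction",
    "fold_discrepancy",
    "respiration_deficient_pct",
    "respiration_regain_pct",
    "fit_standard_curves",
    "mtdna_copy_number",
    "mtdna_bin_comparison",
]


@dataclass(frozen=True)
class SwitchingModelParams:
    """Sub-population composition and kinetics for the state-switching model.

    Parameters
    ----------
    f_low0
        Fraction of low-potential cells at t = 0 (sorting impurity).
    f_slow, f_fast
        Fractions of slow- and fast-growing cells within the high-potential
        pool at t = 0.
    r_slow, r_fast
        Exponential growth rates (h^-1) of the slow and fast sub-populations.
        Low-potential cells are assumed to grow at ``r_fast`` (a conservative
        choice: it maximises the predicted low fraction).
    s_low_to_high
        Fraction of low-potential cells switching to the high state per 24 h.
    t_h
        Prediction horizon in hours.
    strict
        When True (default) require the three t=0 fractions to sum to 1.
        The relaxed mode exists because one published evaluation of the
        second growth interval enters per-term fractions that do not
        renormalise (see :func:`second_day_prediction`).
    """

    f_low0: float
    f_slow: float
    f_fast: float
    r_slow: float = 0.20
    r_fast: float = 0.37
    s_low_to_high: float = 0.1
    t_h: float = 24.0
    strict: bool = True

    def __post_init__(self) -> None:
        for name in ("f_low0", "f_slow", "f_fast"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.r_slow < 0 or self.r_fast < 0:
            raise ValueError("growth rates must be >= 0")
        if not 0.0 <= self.s_low_to_high <= 1.0:
            raise ValueError("s_low_to_high must be in [0, 1]")
        total = self.f_low0 + self.f_slow + self.f_fast
        if self.strict and abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1 (got {total}); "
                             "pass strict=False for per-term evaluation")


#: t = 0 composition of the HI-sorted bin: 1% low-potential impurity,
#: 80% slow / 19% fast high-potential cells, 10%/24 h low-to-high switching.
HI_BIN_DAY1 = SwitchingModelParams(f_low0=0.01, f_slow=0.80, f_fast=0.19)


def predict_low_state_fraction(params: SwitchingModelParams) -> float:
    """Predicted % of low-potential cells after ``t_h`` hours of growth.

    All sub-populations grow exponentially and no cell switches from the
    high to the low state; a fraction ``s_low_to_high`` of the grown
    low-potential pool is removed (switched away) over the horizon::

        % low = 100 * f_low0*e^(r_f*t)*(1 - s)
                / (f_slow*e^(r_s*t) + f_fast*e^(r_f*t) + f_low0*e^(r_f*t))
    """
    t = params.t_h
    low = params.f_low0 * math.exp(params.r_fast * t)
    slow = params.f_slow * math.exp(params.r_slow * t)
    fast = params.f_fast * math.exp(params.r_fast * t)
    # per-24 h switching fraction rescaled to the horizon via the exponential
    # hazard (equals s_low_to_high exactly at t = 24 h, 0 at t = 0)
    scale = 1.0 - (1.0 - params.s_low_to_high) ** (t / 24.0)
    numer = low - scale * low
    denom = slow + fast + low
    return 100.0 * numer / denom


def second_day_prediction(
    f_low0: float = 0.347,
    carryover: float = 0.653,
    slow_within: float = 0.80,
    fast_within: float = 0.20,
    printed_arithmetic: bool = True,
    **kwargs,
) -> float:
    """Low-state % for the 24-to-48 h interval, starting from the observed
    24 h composition (34.7% low-potential cells).

    The high-potential remainder (``carryover`` = 0.653) splits 80/20 into
    slow and fast growers.  Two term conventions exist for the fast
    high-potential denominator term:

    - ``printed_arithmetic=True``: the fast term is ``0.20 * e^(r_f*24)``,
      without the carry-over factor — this reproduces the published 56.2%.
    - ``printed_arithmetic=False``: the symbol-faithful
      ``0.20 * 0.653 * e^(r_f*24)``, which yields a larger fraction (~64%).

    Both are provided because the source arithmetic and its displayed
    symbols disagree; which was intended cannot be determined.
    """
    f_fast = fast_within if printed_arithmetic else fast_within * carryover
    params = SwitchingModelParams(
        f_low0=f_low0,
        f_slow=slow_within * carryover,
        f_fast=f_fast,
        strict=False,
        **kwargs,
    )
    return predict_low_state_fraction(params)


def fold_discrepancy(observed_pct: float, predicted_pct: float) -> tuple[float, int]:
    """Observed/predicted ratio, plus its nearest integer fold."""
    if predicted_pct <= 0:
        raise ValueError("predicted percentage must be > 0 for a fold ratio")
    fold = observed_pct / predicted_pct
    return fold, int(round(fold))


def quantile_bins(
    intensity: np.ndarray,
    bin_fraction: float = 0.05,
    gate_positions: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0),
) -> dict[str, np.ndarray]:
    """Index sets of the HI/M1/M2/LO quantile gates on a signal vector.

    ``HI`` is the top ``bin_fraction`` of cells by intensity, ``LO`` the
    bottom; ``M1`` and ``M2`` are equally sized gates whose top edges sit at
    ``gate_positions`` (fractions of the population, counted from the top).
    Ties are broken deterministically by input order (stable sort).
    """
    intensity = np.asarray(intensity, dtype=float)
    n = intensity.size
    if n < 4 / bin_fraction:
        raise ValueError(f"need at least {math.ceil(4 / bin_fraction)} cells "
                         f"for four {bin_fraction:.0%} bins")
    k = math.ceil(bin_fraction * n)
    # stable sort descending: sort ascending on -intensity keeps input order on ties
    order = np.argsort(-intensity, kind="stable")
    starts = {
        "HI": 0,
        "M1": int(gate_positions[0] * n),
        "M2": int(gate_positions[1] * n),
        "LO": n - k,
    }
    bins: dict[str, np.ndarray] = {}
    taken: set[int] = set()
    for name in ("HI", "M1", "M2", "LO"):
        idx = order[starts[name]:starts[name] + k]
        if taken.intersection(idx.tolist()):
            raise ValueError("gate positions produce overlapping bins")
        taken.update(idx.tolist())
        bins[name] = idx
    return bins


def respiration_deficient_pct(n_small: int, n_big: int) -> float:
    """% respiration-deficient (petite) cells from colony counts on
    glycerol+glucose plates: 100 * small / (small + big)."""
    total = n_small + n_big
    if total <= 0:
        raise ValueError("need at least one colony")
    return 100.0 * n_small / total


def respiration_regain_pct(
    n_scdg_respiring: int, n_scg: int, n_scdg_total: int
) -> float:
    """% of cells regaining respiration capability.

    SCDG plates (glycerol + a little glucose) grow every cell; SCG plates
    (glycerol only) grow only cells respiring at plating.  The difference,
    over the SCDG total, is the regain percentage.  A negative value (more
    SCG than SCDG-respiring colonies, i.e. counting noise) is returned
    as-is with a warning rather than clipped.
    """
    if n_scdg_total <= 0:
        raise ValueError("n_scdg_total must be > 0")
    pct = 100.0 * (n_scdg_respiring - n_scg) / n_scdg_total
    if pct < 0:
        warnings.warn(
            f"negative regain percentage ({pct:.2f}%): SCG count exceeds "
            "SCDG respiring count (counting noise)", stacklevel=2)
    return pct


# --------------------------------------------------------------------------
# qPCR absolute quantification


@dataclass
class QpcrPlate:
    """One sample's qPCR reactions: per-primer standard dilution series plus
    technical-replicate sample Cts, for mitochondrial and nuclear primers.

    ``data`` columns: primer, target ("mt"|"nuclear"), role
    ("standard"|"sample"), quantity (known input amount; NaN for samples),
    ct.
    """

    data: pd.DataFrame
    label: str = "sample"

    REQUIRED = ("primer", "target", "role", "quantity", "ct")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ValueError(f"plate table missing columns: {sorted(missing)}")
        bad = set(self.data["target"]) - {"mt", "nuclear"}
        if bad:
            raise ValueError(f"unknown primer targets: {sorted(bad)}")


@dataclass
class QpcrResult:
    copy_number: float
    sd: float
    mean_mt: float
    mean_nuclear: float
    per_primer: pd.DataFrame = field(repr=False)
    excluded_primers: list[str] = field(default_factory=list)


def fit_standard_curves(plate: QpcrPlate, r2_min: float = 0.98) -> pd.DataFrame:
    """OLS of Ct on log10(quantity) per primer over the dilution series.

    Returns a frame (primer, target, slope, intercept, r2, ok); primers
    whose fit falls below ``r2_min`` are flagged not-ok.
    """
    rows = []
    std = plate.data[plate.data["role"] == "standard"]
    for (primer, target), grp in std.groupby(["primer", "target"], sort=True):
        x = np.log10(grp["quantity"].to_numpy(dtype=float))
        y = grp["ct"].to_numpy(dtype=float)
        res = stats.linregress(x, y)
        r2 = res.rvalue ** 2
        rows.append({"primer": primer, "target": target,
                     "slope": res.slope, "intercept": res.intercept,
                     "r2": r2, "ok": bool(r2 >= r2_min)})
    return pd.DataFrame(rows)


def mtdna_copy_number(plate: QpcrPlate, r2_min: float = 0.98,
                      min_primers: int = 3) -> QpcrResult:
    """mtDNA copies per nuclear genome from a qPCR plate.

    Each primer's standard curve converts sample Cts back to absolute
    quantities (per technical replicate, then averaged per primer).  The
    copy number is the ratio of the mt-class to nuclear-class mean
    quantity; its s.d. comes from first-order (delta-method) propagation of
    the two class-level standard deviations::

        sd_ratio = ratio * sqrt((sd_mt/mean_mt)^2 + (sd_nuc/mean_nuc)^2)

    Primers with a failing standard curve (R^2 < ``r2_min``) are excluded
    with a warning; fewer than ``min_primers`` surviving in either class is
    an error.
    """
    curves = fit_standard_curves(plate, r2_min=r2_min)
    excluded = curves.loc[~curves["ok"], "primer"].tolist()
    if excluded:
        warnings.warn(f"excluding primers with poor standard curves: {excluded}",
                      stacklevel=2)
    good = curves[curves["ok"]].set_index("primer")
    samples = plate.data[plate.data["role"] == "sample"]
    rows = []
    for (primer, target), grp in samples.groupby(["primer", "target"], sort=True):
        if primer not in good.index:
            continue
        slope = good.at[primer, "slope"]
        intercept = good.at[primer, "intercept"]
        q = 10.0 ** ((grp["ct"].to_numpy(dtype=float) - intercept) / slope)
        rows.append({"primer": primer, "target": target,
                     "quantity": float(np.mean(q)),
                     "quantity_sd": float(np.std(q, ddof=1)) if len(q) > 1 else 0.0})
    per_primer = pd.DataFrame(rows)
    for target in ("mt", "nuclear"):
        if (per_primer["target"] == target).sum() < min_primers:
            raise ValueError(f"fewer than {min_primers} usable {target} primers")
    mt = per_primer.loc[per_primer["target"] == "mt", "quantity"].to_numpy()
    nuc = per_primer.loc[per_primer["target"] == "nuclear", "quantity"].to_numpy()
    mean_mt, mean_nuc = float(np.mean(mt)), float(np.mean(nuc))
    sd_mt = float(np.std(mt, ddof=1))
    sd_nuc = float(np.std(nuc, ddof=1))
    ratio = mean_mt / mean_nuc
    sd = ratio * math.sqrt((sd_mt / mean_mt) ** 2 + (sd_nuc / mean_nuc) ** 2)
    return QpcrResult(copy_number=ratio, sd=sd, mean_mt=mean_mt,
                      mean_nuclear=mean_nuc, per_primer=per_primer,
                      excluded_primers=excluded)


def mtdna_bin_comparison(
    plates: dict[str, QpcrPlate],
    reference_bin: str = "LO",
    r2_min: float = 0.98,
) -> pd.DataFrame:
    """Compare mt vs nuclear quantities across sorted bins.

    All per-primer quantities are normalised by the reference bin's value
    for the same primer; per bin, a two-sample t-test asks whether the
    normalised mt values differ from the normalised nuclear values.
    Returns a frame (bin, copy_number, sd, p_mt_vs_nuclear).
    """
    if reference_bin not in plates:
        raise ValueError(f"reference bin {reference_bin!r} not among plates")
    results = {name: mtdna_copy_number(p, r2_min=r2_min) for name, p in plates.items()}
    ref = results[reference_bin].per_primer.set_index("primer")["quantity"]
    rows = []
    for name, res in results.items():
        pp = res.per_primer.set_index("primer")
        norm = pp["quantity"] / ref.reindex(pp.index)
        mt = norm[pp["target"] == "mt"].dropna().to_numpy()
        nuc = norm[pp["target"] == "nuclear"].dropna().to_numpy()
        if name == reference_bin:  # trivially all ones against itself
            t_p = float("nan")
        else:
            t_p = float(stats.ttest_ind(mt, nuc).pvalue)
        rows.append({"bin": name, "copy_number": res.copy_number, "sd": res.sd,
                     "p_mt_vs_nuclear": t_p})
    return pd.DataFrame(rows)
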