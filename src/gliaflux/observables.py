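"""Per-solution observables and ensemble statistics.

Definitions (flux components located through the network role index):

* OGI, the oxygen-to-glucose index: ``nuO2(->c) / nuGlc(->c)`` -- the ratio
  of the capillary oxygen and glucose uptakes (CMRO2 / CMRGlc).  6 is the
  stoichiometric ceiling for complete aerobic oxidation of glucose; values
  slightly above 6 can occur because the oxygen intake is a free variable
  and intracellular oxygen may accumulate under the soft constraints.
* V_cyc, the glutamate-glutamine cycle rate: the astrocytic glutamine
  synthetase flux ``nuGS(a)``.
* CMR_Glc(ox)(n), neuronal oxidative glucose use: ``nuPDH(n) / 2`` (two
  pyruvates per glucose).
* astrocytic glucose fraction: ``(nuGlc(c->a) + nuGlc(e->a)) / nuGlc(->c)``.
* CCLS flux: net astrocyte-to-neuron lactate flow, reported on the
  astrocyte side (positive = ANLS, negative = NALS); the neuron-side value
  is stored alongside because extracellular lactate may be weakly
  net-produced under the soft constraints.

A solution is *active* when V_cyc exceeds the null-flux threshold 1e-6
(strict inequality; at or below is silent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .network import MetabolicNetwork, MissingRoleError
from .sampling import SolutionEnsemble

__all__ = [
    "NULL_FLUX_THRESHOLD",
    "ObservableRecord",
    "ConditionalCurve",
    "CorrelationMatrix",
    "compute_ogi",
    "compute_vcyc",
    "compute_cmr_glc_ox_n",
    "glucose_partition",
    "ccls_flux",
    "oxygen_consumption",
    "classify_active",
    "compute_observables",
    "conditional_average",
    "piecewise_slopes",
    "pearson_matrix",
    "correlation_histograms",
    "ogi_distribution",
    "basal_calibration",
]

#: fluxes smaller than this are treated as null
NULL_FLUX_THRESHOLD = 1e-6

ACTIVATED_UPTAKE_FACTOR = 1.15  # activated state = +15% glucose uptake


def _role_flux(nu: np.ndarray, net: MetabolicNetwork, role: str) -> float:
    return float(nu[net.role_column(role)])


def _role_flux_or_zero(nu: np.ndarray, net: MetabolicNetwork, role: str) -> float:
    try:
        return _role_flux(nu, net, role)
    except MissingRoleError:
        return 0.0


def compute_ogi(nu: np.ndarray, net: MetabolicNetwork) -> float:
    """Oxygen-to-glucose index of one flux configuration."""
    glc = _role_flux(nu, net, "GLC_to_c")
    if glc <= 0:
        raise ValueError("OGI undefined: glucose intake is not positive")
    return _role_flux(nu, net, "O2_to_c") / glc


def compute_vcyc(nu: np.ndarray, net: MetabolicNetwork) -> float:
    """Glutamate-glutamine cycle rate = astrocytic glutamine synthetase flux."""
    return _role_flux(nu, net, "GS_a")


def compute_cmr_glc_ox_n(nu: np.ndarray, net: MetabolicNetwork) -> float:
    """Neuronal oxidative glucose use: half the neuronal PDH flux."""
    return 0.5 * _role_flux(nu, net, "PDH_n")


def glucose_partition(nu: np.ndarray, net: MetabolicNetwork) -> float:
    """Astrocytic share of total glucose uptake, in [0, 1]."""
    glc = _role_flux(nu, net, "GLC_to_c")
    if glc <= 0:
        raise ValueError("partition undefined: glucose intake is not positive")
    astro = _role_flux_or_zero(nu, net, "GLC_c_to_a") + _role_flux_or_zero(
        nu, net, "GLC_e_to_a"
    )
    return astro / glc


def ccls_flux(nu: np.ndarray, net: MetabolicNetwork) -> float:
    """Net astrocyte-to-neuron lactate flux (astrocyte-side, positive = ANLS)."""
    return _role_flux(nu, net, "LAC_a_to_n")


def ccls_flux_neuron_side(nu: np.ndarray, net: MetabolicNetwork) -> float:
    """Neuron-side CCLS value: net lactate import by the neuron."""
    return -_role_flux(nu, net, "LAC_n_to_e")


def oxygen_consumption(nu: np.ndarray, net: MetabolicNetwork, cell: str) -> float:
    """Total O2 actually consumed by reactions scoped to ``cell``.

    Sums ``-coeff x flux`` over oxygen species with negative contribution.
    Transport, intake and efflux reactions are excluded -- they move oxygen
    between compartments rather than consuming it -- and accumulated
    (non-consumed) oxygen is excluded by construction.
    """
    total = 0.0
    skip = {"transport", "intake", "efflux"}
    for j, r in enumerate(net.reactions):
        if r.cell_scope != cell or r.pathway_tag in skip:
            continue
        for sid, coeff in r.stoichiometry.items():
            if sid.startswith("O2["):
                contrib = float(coeff) * nu[j]
                if contrib < 0:
                    total -= contrib
    return total


def classify_active(
    nu: np.ndarray, net: MetabolicNetwork, theta: float = NULL_FLUX_THRESHOLD
) -> str:
    """'active' iff V_cyc strictly exceeds the null threshold, else 'silent'."""
    return "active" if compute_vcyc(nu, net) > theta else "silent"


@dataclass
class ObservableRecord:
    ogi: float
    vcyc: float
    cmr_glc_ox_n: float
    astro_glc_fraction: float
    lac_a_to_n: float
    lac_n_side: float
    cmro2_n: float
    cmro2_a: float
    active: bool


def compute_observables(
    ensemble: SolutionEnsemble,
    net: MetabolicNetwork,
    theta: float = NULL_FLUX_THRESHOLD,
) -> pd.DataFrame:
    """Per-solution observables of an ensemble as a DataFrame.

    Columns: ogi, vcyc, cmr_glc_ox_n, astro_glc_fraction, lac_a_to_n,
    lac_n_side, cmro2_n, cmro2_a, active, glucose.
    """
    sol = ensemble.solutions
    K = sol.shape[0]
    # vectorized role lookups
    glc = sol[:, net.role_column("GLC_to_c")]
    o2 = sol[:, net.role_column("O2_to_c")]
    try:
        vcyc = sol[:, net.role_column("GS_a")]
        active = vcyc > theta
    except MissingRoleError:  # toy networks without a glutamine synthetase
        vcyc = np.full(K, np.nan)
        active = np.zeros(K, dtype=bool)
    out = pd.DataFrame(
        {
            "ogi": o2 / glc,
            "vcyc": vcyc,
            "active": active,
            "glucose": glc,
        }
    )
    try:
        out["cmr_glc_ox_n"] = 0.5 * sol[:, net.role_column("PDH_n")]
    except MissingRoleError:
        out["cmr_glc_ox_n"] = np.nan
    astro = np.zeros(K)
    for role in ("GLC_c_to_a", "GLC_e_to_a"):
        try:
            astro = astro + sol[:, net.role_column(role)]
        except MissingRoleError:
            pass
    out["astro_glc_fraction"] = astro / glc
    out["lac_a_to_n"] = sol[:, net.role_column("LAC_a_to_n")]
    try:
        out["lac_n_side"] = -sol[:, net.role_column("LAC_n_to_e")]
    except MissingRoleError:
        out["lac_n_side"] = np.nan
    out["cmro2_n"] = [oxygen_consumption(sol[k], net, "neuron") for k in range(K)]
    out["cmro2_a"] = [oxygen_consumption(sol[k], net, "astrocyte") for k in range(K)]
    return out


# ---------------------------------------------------------------------------
# ensemble statistics
# ---------------------------------------------------------------------------


@dataclass
class ConditionalCurve:
    """Binned conditional averages of y over x with standard errors."""

    x_centers: np.ndarray
    y_means: np.ndarray
    y_standard_errors: np.ndarray
    counts: np.ndarray
    condition: str = "all"
    x_field: str = "x"
    y_field: str = "y"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.x_field: self.x_centers,
                self.y_field: self.y_means,
                "se": self.y_standard_errors,
                "n": self.counts,
            }
        )


def _condition_mask(records: pd.DataFrame, condition: str) -> np.ndarray:
    if condition == "all":
        return np.ones(len(records), dtype=bool)
    if condition == "active":
        return records["active"].to_numpy()
    if condition == "silent":
        return ~records["active"].to_numpy()
    raise ValueError(f"unknown condition {condition!r}")


def conditional_average(
    records: pd.DataFrame,
    x_field: str,
    y_field: str,
    condition: str = "all",
    bins: Union[int, float, Sequence[float]] = 20,
) -> ConditionalCurve:
    """Per-bin mean and standard error of y over records meeting the condition.

    ``bins`` may be an integer (equal-count quantile bins), a float (equal
    width) or explicit edges.  Empty selections raise; bins with no records
    are dropped so every reported bin has at least one count.
    """
    mask = _condition_mask(records, condition)
    x = records.loc[mask, x_field].to_numpy(dtype=float)
    y = records.loc[mask, y_field].to_numpy(dtype=float)
    if x.size == 0:
        raise ValueError(f"no records satisfy condition {condition!r}")
    if isinstance(bins, int):
        edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)))
        if len(edges) < 2:  # degenerate x: a single bin holds everything
            edges = np.array([x.min(), x.max() + 1.0])
    elif isinstance(bins, float):
        lo, hi = x.min(), x.max() + bins * 1e-9
        edges = np.arange(lo, hi + bins, bins)
    else:
        edges = np.asarray(bins, dtype=float)
    idx = np.clip(np.digitize(x, edges[1:-1]), 0, len(edges) - 2)
    xc, ym, se, cnt = [], [], [], []
    for b in range(len(edges) - 1):
        m = idx == b
        n = int(m.sum())
        if n == 0:
            continue
        xc.append(float(x[m].mean()))
        ym.append(float(y[m].mean()))
        se.append(float(y[m].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0)
        cnt.append(n)
    return ConditionalCurve(
        np.array(xc), np.array(ym), np.array(se), np.array(cnt),
        condition, x_field, y_field,
    )


def piecewise_slopes(
    curve: ConditionalCurve, breakpoint_x: float
) -> Tuple[float, float]:
    """Weighted least-squares slopes below and above ``breakpoint_x``.

    Weights are 1/se^2 (bins with zero standard error get the largest finite
    weight present).  Requires at least two bins on each side.
    """

    def wls_slope(x: np.ndarray, y: np.ndarray, se: np.ndarray) -> float:
        w = np.where(se > 0, 1.0 / np.maximum(se, 1e-300) ** 2, np.nan)
        if np.isnan(w).all():
            w = np.ones_like(x)
        else:
            w = np.where(np.isnan(w), np.nanmax(w), w)
        W = w.sum()
        xm = (w * x).sum() / W
        ym = (w * y).sum() / W
        denom = (w * (x - xm) ** 2).sum()
        if denom == 0:
            raise ValueError("degenerate x values in slope fit")
        return float((w * (x - xm) * (y - ym)).sum() / denom)

    lo = curve.x_centers <= breakpoint_x
    hi = ~lo
    if lo.sum() < 2 or hi.sum() < 2:
        raise ValueError("need at least two bins on each side of the breakpoint")
    return (
        wls_slope(curve.x_centers[lo], curve.y_means[lo], curve.y_standard_errors[lo]),
        wls_slope(curve.x_centers[hi], curve.y_means[hi], curve.y_standard_errors[hi]),
    )


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson coefficients over a conditioned solution subset."""

    values: np.ndarray  # (N, N) with NaN on masked entries
    null_mask: np.ndarray  # True where the reaction is null in the subset
    condition: str
    reaction_ids: List[str] = field(default_factory=list)


def pearson_matrix(
    ensemble: Union[SolutionEnsemble, np.ndarray],
    net: MetabolicNetwork,
    condition: str = "all",
    theta: float = NULL_FLUX_THRESHOLD,
) -> CorrelationMatrix:
    """Pearson coefficients for each pair of reactions in a conditioned subset.

    Conditioning is on V_cyc: 'all' keeps every solution, 'active' those
    with V_cyc > theta, 'silent' those with V_cyc <= theta.  Reactions whose
    flux magnitude stays below theta in every conditioned solution, or whose
    flux has zero variance, are masked (NaN), not propagated as NaN noise.
    """
    sol = ensemble.solutions if isinstance(ensemble, SolutionEnsemble) else ensemble
    if condition == "all":
        m = np.ones(sol.shape[0], dtype=bool)
    elif condition == "active":
        m = sol[:, net.role_column("GS_a")] > theta
    elif condition == "silent":
        m = sol[:, net.role_column("GS_a")] <= theta
    else:
        raise ValueError(f"unknown condition {condition!r}")
    sub = sol[m]
    if sub.shape[0] < 10:
        raise ValueError(
            f"conditioned subset has {sub.shape[0]} solutions; need >= 10"
        )
    null = np.max(np.abs(sub), axis=0) < theta
    # near-constant columns (e.g. pinned fluxes with 1e-13 projection noise)
    # would overflow the correlation normalization; mask them too
    degenerate = np.std(sub, axis=0) <= 1e-12
    masked = null | degenerate
    keep = ~masked
    values = np.full((sol.shape[1], sol.shape[1]), np.nan)
    if keep.sum() >= 2:
        corr = np.corrcoef(sub[:, keep], rowvar=False)
        values[np.ix_(keep, keep)] = corr
    elif keep.sum() == 1:
        j = int(np.nonzero(keep)[0][0])
        values[j, j] = 1.0
    return CorrelationMatrix(values, masked, condition, [r.id for r in net.reactions])


def correlation_histograms(
    cm: CorrelationMatrix,
    net: MetabolicNetwork,
    bins: Union[int, Sequence[float]] = 20,
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Histogram summaries of pairwise correlations.

    Pairs are grouped into within-neuron, within-astrocyte and between-cell
    classes by the reactions' cell scopes; masked (null) reactions are
    excluded.  Returns {group: (edges, density)}.
    """
    scope = np.array([r.cell_scope for r in net.reactions])
    keep = ~cm.null_mask
    groups: Dict[str, List[float]] = {
        "within_neuron": [],
        "within_astrocyte": [],
        "between_cells": [],
    }
    idx = np.nonzero(keep)[0]
    for a_pos, i in enumerate(idx):
        for j in idx[a_pos + 1 :]:
            si, sj = scope[i], scope[j]
            if si == "neuron" and sj == "neuron":
                key = "within_neuron"
            elif si == "astrocyte" and sj == "astrocyte":
                key = "within_astrocyte"
            elif {si, sj} == {"neuron", "astrocyte"}:
                key = "between_cells"
            else:
                continue
            groups[key].append(cm.values[i, j])
    edges = np.linspace(-1, 1, bins + 1) if isinstance(bins, int) else np.asarray(bins)
    out = {}
    for key, vals in groups.items():
        dens, _ = np.histogram(vals, bins=edges, density=True)
        out[key] = (edges, dens)
    return out


def ogi_distribution(
    ensemble: SolutionEnsemble,
    net: MetabolicNetwork,
    bin_width: float = 0.05,
) -> Tuple[np.ndarray, np.ndarray, float, float]:
    """Normalized histogram of per-solution OGI; returns (edges, density,
    mean, standard error of the mean)."""
    sol = ensemble.solutions
    ogi = sol[:, net.role_column("O2_to_c")] / sol[:, net.role_column("GLC_to_c")]
    lo = np.floor(ogi.min() / bin_width) * bin_width
    hi = np.ceil(ogi.max() / bin_width) * bin_width + bin_width / 2
    edges = np.arange(lo, hi, bin_width)
    if len(edges) < 2:
        edges = np.array([lo - bin_width / 2, lo + bin_width / 2])
    density, _ = np.histogram(ogi, bins=edges, density=True)
    return edges, density, float(ogi.mean()), float(ogi.std(ddof=1) / np.sqrt(len(ogi)))


def basal_calibration(
    glucose_levels: Sequence[float],
    mean_ogis: Sequence[float],
    target_ogi: float = 5.5,
) -> Tuple[float, float]:
    """Interpolate the glucose uptake at which the ensemble-mean OGI equals
    the awake resting value (5.5); the activated level is 15% above it.

    Requires the sweep to bracket the target; mean OGI is expected to
    decrease with uptake.
    """
    g = np.asarray(glucose_levels, dtype=float)
    o = np.asarray(mean_ogis, dtype=float)
    order = np.argsort(g)
    g, o = g[order], o[order]
    if not (o.min() <= target_ogi <= o.max()):
        raise ValueError(
            f"sweep mean OGIs [{o.min():.3g}, {o.max():.3g}] do not bracket "
            f"{target_ogi}"
        )
    # interpolate on the (decreasing) OGI axis
    g_star = float(np.interp(-target_ogi, -o, g))
    return g_star, ACTIVATED_UPTAKE_FACTOR * g_star
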