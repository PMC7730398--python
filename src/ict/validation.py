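"""Strain-measurement accuracy assessment with synthetic deformations.

Known uniform strains are injected into a reference volume by resampling,
the full tracking chain is run against the reference, and the recovered
strains are compared with the imposed values.  *Absolute* accuracy deforms
the reference state itself; *differential* accuracy deforms an independent
second acquisition (fresh noise realization) and subtracts the chain's
estimate of the undeformed second state, which additionally exposes the
chain to acquisition-to-acquisition variability.

The report keeps the full error table per parameter, cell type and strain
level rather than a single pass/fail, so regressions stay visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import GrayVolume, GroundTruth, add_acquisition_noise, \
    apply_affine_deformation
from .pipeline import ChainConfig, SegmentedState, pair_strain, segment_state

__all__ = ["AccuracyReport", "absolute_accuracy", "differential_accuracy",
           "measure_pair"]

#: parameter -> (branch, sample column, which imposed component it estimates)
_PARAMS = {
    "eps_RR": ("tracheid", "eps_RR", "RR"),
    "eps_TT": ("tracheid", "eps_TT", "TT"),
    "eps_LL": ("tracheid", "eps_LL", "LL"),
    "eps_sigma": ("tracheid", "eps_sigma_cell", "area"),
    "eps_t": ("tracheid", "eps_t_cell", "iso"),
    "ray_eps_LL": ("ray", "eps_RR", "LL"),
    "ray_eps_RR": ("ray", "eps_LL", "RR"),
}


@dataclass
class AccuracyReport:
    """Tidy error table: one row per (parameter, level)."""

    table: pd.DataFrame
    kind: str = "absolute"

    def errors(self, parameter: str) -> pd.DataFrame:
        return self.table[self.table.parameter == parameter]


def _true_value(component: str, eps: np.ndarray) -> float:
    if component == "RR":
        return float(eps[0, 0])
    if component == "TT":
        return float(eps[1, 1])
    if component == "LL":
        return float(eps[2, 2])
    if component == "area":
        return float((1 + eps[0, 0]) * (1 + eps[1, 1]) - 1)
    if component == "iso":
        return float(0.5 * (eps[0, 0] + eps[1, 1]))
    raise KeyError(component)


def measure_pair(
    ref_state: SegmentedState,
    test_state: SegmentedState,
    config: ChainConfig,
    parameters=None,
) -> dict[str, pd.Series]:
    """Run both branches on a state pair; per-parameter sample series."""
    parameters = parameters or list(_PARAMS)
    out: dict[str, pd.Series] = {}
    cache: dict[str, pd.DataFrame | None] = {}
    for p in parameters:
        branch, col, _ = _PARAMS[p]
        if branch not in cache:
            _, samples = pair_strain(ref_state, test_state, config,
                                     branch=branch)
            cache[branch] = samples
        samples = cache[branch]
        if samples is None or len(samples) == 0 or col not in samples:
            out[p] = pd.Series(dtype=float)
            continue
        vals = samples[col]
        if p == "eps_t":
            vals = vals[samples["eps_t"].notna()]
        out[p] = vals.dropna()
    return out


def absolute_accuracy(
    vol: GrayVolume,
    gt: GroundTruth,
    strain_levels,
    directions=("R", "L"),
    config: ChainConfig | None = None,
    parameters=None,
    seed: int = 0,
) -> AccuracyReport:
    """Absolute accuracy: chain(reference + synthetic) vs reference.

    For each level and direction the reference volume is resampled through
    the affine map, the chain (segment, match, track, strain) is run
    against the reference segmentation, and the per-parameter median and
    mean absolute errors against the imposed strain are tabulated.
    """
    config = config or ChainConfig()
    ref_state = segment_state(vol, config)
    rows = []
    for level in strain_levels:
        eps = np.zeros((3, 3))
        if "R" in directions:
            eps[0, 0] = level
        if "T" in directions:
            eps[1, 1] = level
        if "L" in directions:
            eps[2, 2] = level
        vol_d, _ = apply_affine_deformation(vol, gt, eps)
        test_state = segment_state(vol_d, config,
                                   threshold=ref_state.binary.threshold)
        series = measure_pair(ref_state, test_state, config, parameters)
        for p, vals in series.items():
            truth = _true_value(_PARAMS[p][2], eps)
            err = (vals - truth).abs()
            rows.append(dict(
                parameter=p, level=level, true=truth,
                estimate=float(vals.median()) if len(vals) else np.nan,
                median_abs_error=float(err.median()) if len(err) else np.nan,
                mean_abs_error=float(err.mean()) if len(err) else np.nan,
                n=int(len(vals)),
            ))
    return AccuracyReport(table=pd.DataFrame(rows), kind="absolute")


def differential_accuracy(
    vol: GrayVolume,
    gt: GroundTruth,
    strain_levels,
    second: GrayVolume | None = None,
    directions=("R", "L"),
    config: ChainConfig | None = None,
    parameters=None,
    seed: int = 1,
) -> AccuracyReport:
    """Differential accuracy: [chain(#2 + synthetic) - chain(#2)] vs #1.

    ``second`` is the independent re-acquisition #2; when omitted, a fresh
    noise realization of the reference volume stands in for it.  The
    imposed strain is recovered as the difference of the two chain runs, so
    acquisition differences between #1 and #2 enter twice.
    """
    config = config or ChainConfig()
    if second is None:
        # stand-in for a true re-acquisition: an independent noise
        # realization at the full acquisition noise level (conservative:
        # the reference noise cannot be removed, so the pair carries more
        # total noise than two real acquisitions would)
        second = add_acquisition_noise(vol, noise_sd=8.0, seed=seed)
    ref_state = segment_state(vol, config)
    second_state = segment_state(second, config,
                                 threshold=ref_state.binary.threshold)
    base = measure_pair(ref_state, second_state, config, parameters)
    rows = []
    for level in strain_levels:
        eps = np.zeros((3, 3))
        if "R" in directions:
            eps[0, 0] = level
        if "T" in directions:
            eps[1, 1] = level
        if "L" in directions:
            eps[2, 2] = level
        second_d, _ = apply_affine_deformation(second, gt, eps)
        test_state = segment_state(second_d, config,
                                   threshold=ref_state.binary.threshold)
        series = measure_pair(ref_state, test_state, config, parameters)
        for p, vals in series.items():
            truth = _true_value(_PARAMS[p][2], eps)
            baseline = float(base[p].median()) if len(base.get(p, [])) else 0.0
            delta = vals - baseline
            err = (delta - truth).abs()
            rows.append(dict(
                parameter=p, level=level, true=truth,
                estimate=float(delta.median()) if len(delta) else np.nan,
                median_abs_error=float(err.median()) if len(err) else np.nan,
                mean_abs_error=float(err.mean()) if len(err) else np.nan,
                n=int(len(vals)),
            ))
    return AccuracyReport(table=pd.DataFrame(rows), kind="differential")
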