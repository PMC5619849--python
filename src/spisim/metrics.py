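"""Run-to-run consistency of EMC volumes and ensemble summary statistics.

The coefficient of variation sigma_v measures how consistently independent
EMC runs (different random initializations on the same patterns) reconstruct
the diffraction volume: per voxel, the RMS deviation of the N run intensities
about their mean (1/N convention), normalized by that mean, then averaged
over the voxels of each resolution shell q in [q_k, q_k + dq).  sigma_v = 0
means perfectly consistent runs; sigma_v ~ 1 means run-to-run variation of
the same magnitude as the signal itself.  Because EMC output has an
arbitrary global orientation, volumes are rotationally pre-aligned to the
first run by default before the voxel-wise comparison.

Also here: the per-ensemble summary (photons per pulse, detected photons per
pattern, scattering efficiency, mid-pulse bound electrons) and the two
pattern-rescaling experiments used to compare pulse durations at matched
photon statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .emc import DiffractionVolume, align_volumes

__all__ = [
    "ConsistencyReport",
    "RunSummary",
    "coefficient_of_variation",
    "run_summary",
    "rescale_mean",
    "rescale_mean_rms",
]


@dataclass
class ConsistencyReport:
    """sigma_v per resolution shell over N reconstruction runs."""

    q_centres: np.ndarray        # 1/A
    sigma_v: np.ndarray
    rms_spread: np.ndarray       # RMS of per-voxel CV about the shell mean
    voxel_counts: np.ndarray     # M_q per shell
    n_runs: int
    aligned: bool
    n_excluded: int = 0          # zero-mean voxels excluded

    def half_period_A(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.where(self.q_centres > 0, np.pi / self.q_centres, np.inf)

    def to_frame(self) -> pd.DataFrame:
        dq = self.q_centres[1] - self.q_centres[0] if len(self.q_centres) > 1 else 1.0
        return pd.DataFrame(
            {
                "pixel_radius": self.q_centres / dq,
                "q_invA": self.q_centres,
                "half_period_A": self.half_period_A(),
                "sigma_v": self.sigma_v,
                "rms_spread": self.rms_spread,
                "M_q": self.voxel_counts,
            }
        )


def coefficient_of_variation(
    volumes,
    n_shells: int | None = None,
    align: bool = True,
    ddof_style_sample: bool = False,
    align_level: int = 2,
) -> ConsistencyReport:
    """sigma_v(q): shell-averaged normalized RMS variation of N volumes.

    Per voxel v: sqrt(mean_i (I_i(v) - Ibar(v))^2) / Ibar(v) with the 1/N
    population convention (``ddof_style_sample`` switches to 1/(N-1)); shell
    width defaults to one voxel q-increment.  Voxels with zero mean are
    excluded and counted.  With ``align`` (default) every volume is first
    rotated to best match the first.
    """
    volumes = list(volumes)
    if len(volumes) < 2:
        raise ValueError("need at least two volumes")
    n = volumes[0].n
    dq = volumes[0].dq
    for v in volumes[1:]:
        if v.n != n or not np.isclose(v.dq, dq):
            raise ValueError("volumes must share one grid")

    if align:
        ref = volumes[0]
        volumes = [ref] + [
            align_volumes(v, ref, level=align_level)[0] for v in volumes[1:]
        ]

    stack = np.stack([v.data for v in volumes])  # (N, n, n, n)
    N = len(volumes)
    mean = stack.mean(axis=0)
    ddof = 1 if ddof_style_sample else 0
    dev = np.sqrt(((stack - mean) ** 2).sum(axis=0) / (N - ddof))

    qmag = volumes[0].qmag_grid()
    c = n // 2
    interior = qmag <= c * dq + 1e-12
    n_shells = n_shells or (c + 1)
    shell = np.minimum((qmag / dq).astype(int), n_shells - 1)

    valid = interior & (mean > 0)
    n_excluded = int(interior.sum() - valid.sum())
    cv = np.zeros_like(mean)
    cv[valid] = dev[valid] / mean[valid]
    cv[cv < 1e-13] = 0.0  # accumulation rounding, not run-to-run signal

    sigma_v = np.zeros(n_shells)
    spread = np.zeros(n_shells)
    counts = np.zeros(n_shells, dtype=int)
    for s in range(n_shells):
        m = valid & (shell == s)
        counts[s] = m.sum()
        if counts[s]:
            vals = cv[m]
            sigma_v[s] = vals.mean()
            spread[s] = vals.std()
    q_centres = (np.arange(n_shells) + 0.5) * dq
    return ConsistencyReport(
        q_centres=q_centres,
        sigma_v=sigma_v,
        rms_spread=spread,
        voxel_counts=counts,
        n_runs=N,
        aligned=align,
        n_excluded=n_excluded,
    )


@dataclass
class RunSummary:
    """Ensemble summary: photons in, photons detected, scattering efficiency,
    and mid-pulse bound electrons (and its square, the coherent-signal
    scale)."""

    n_ph_pulse: float
    n_ph_det: float
    efficiency: float
    n_e_bound_mid: float
    n_e_bound_mid_sq: float
    n_patterns: int
    valid: bool = True


def run_summary(pulses, trajectories, counts) -> RunSummary:
    """Summarize one ensemble (pulses, damage trajectories, detected counts).

    ``counts`` is (n_patterns, n_pix).  Mid-pulse is the snapshot nearest the
    intensity-weighted median time of the mean pulse, robust for asymmetric
    SASE profiles.
    """
    pulses = list(pulses)
    trajectories = list(trajectories)
    counts = np.asarray(counts)
    if not pulses or not trajectories or counts.size == 0:
        raise ValueError("empty inputs")

    n_ph_pulse = float(np.mean([p.total_photons for p in pulses]))
    n_ph_det = float(counts.sum(axis=1).mean())
    efficiency = n_ph_det / n_ph_pulse
    valid = 0.0 < efficiency < 1.0

    mids = []
    for tr in trajectories:
        # intensity-weighted median time of the matching pulse window
        p = pulses[0]
        cum = np.cumsum(p.intensities)
        t_med = np.interp(0.5 * cum[-1], cum, p.times)
        i_mid = int(np.argmin(np.abs(tr.snapshot_times - t_med)))
        mids.append(tr.z_bound[i_mid].sum())
    n_e_mid = float(np.mean(mids))
    return RunSummary(
        n_ph_pulse=n_ph_pulse,
        n_ph_det=n_ph_det,
        efficiency=efficiency,
        n_e_bound_mid=n_e_mid,
        n_e_bound_mid_sq=n_e_mid**2,
        n_patterns=len(counts),
        valid=valid,
    )


def rescale_mean(counts, target_mean_total: float):
    """Multiply every pixel of every pattern by one global factor so the
    average total photon count matches the target.  Returns (patterns,
    factor)."""
    counts = np.asarray(counts, dtype=float)
    if target_mean_total <= 0:
        raise ValueError("target mean must be positive")
    source_mean = counts.sum(axis=1).mean()
    if source_mean == 0:
        raise ValueError("source patterns carry no photons")
    factor = target_mean_total / source_mean
    return counts * factor, factor


def rescale_mean_rms(counts, target_mean_total: float, target_rms_total: float):
    """Per-pattern factors matching both the mean and the centred RMS of the
    total photon counts to the targets.

    Pattern d with total c_d gets factor
    s_d = [mu_t + (c_d - mu_s) sigma_t / sigma_s] / c_d;
    zero-total patterns are dropped and counted.  Returns
    (patterns, factors, n_dropped).
    """
    counts = np.asarray(counts, dtype=float)
    if target_mean_total <= 0 or target_rms_total < 0:
        raise ValueError("targets must be positive")
    totals = counts.sum(axis=1)
    keep = totals > 0
    n_dropped = int((~keep).sum())
    counts = counts[keep]
    totals = totals[keep]
    mu_s = totals.mean()
    sigma_s = totals.std()
    if sigma_s == 0:
        raise ValueError("degenerate source spread: all pattern totals equal")
    s = (target_mean_total + (totals - mu_s) * target_rms_total / sigma_s) / totals
    if np.any(s < 0):
        raise ValueError("rescaling would produce negative patterns")
    return counts * s[:, None], s, n_dropped
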