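"""End-to-end experiment orchestration: pulses -> damage -> patterns -> EMC
-> consistency reports, from a single run configuration.

The default configuration mirrors the reference ensemble sizes (40 pulses x
25 damage trajectories per pulse = 1000 damage runs, 200 patterns per
trajectory, 5 EMC runs); reduced ensembles for desk-scale runs are set
explicitly.  Every artefact carries provenance: a config hash and
counter-derived per-stage seeds, so a rerun with the same configuration is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import damage as dmg
from . import diffraction as dfr
from . import emc as emc_mod
from . import metrics as met
from . import pulse as pls
from . import sample as smp

__all__ = ["RunConfig", "run_experiment", "compare_durations", "stage_seed"]

_STAGES = {"structure": 0, "pulse": 1, "damage": 2, "pattern": 3, "emc": 4}


def stage_seed(master_seed: int, stage: str, item: int = 0) -> int:
    """Counter-based derivation of per-stage, per-item seeds (< 2^31)."""
    ss = np.random.SeedSequence([int(master_seed), _STAGES[stage], int(item)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """One experiment: pulse parameters, sample, ensembles, detector, seeds."""

    fwhm_fs: float = 3.0
    photons_per_pulse: float = 1e11
    photon_energy_keV: float = 4.96
    coherence_time_fs: float = 0.25
    n_pulses: int = 40
    n_trajectories_per_pulse: int = 25
    n_patterns_per_trajectory: int = 200
    n_emc_runs: int = 5
    # sample: a PDB path, or pseudo-protein fixture parameters
    pdb_path: str | None = None
    fixture_n_atoms: int = 500
    fixture_radius_A: float = 20.0
    # detector block
    n_rows: int = 80
    n_cols: int = 80
    pixel_size_um: float = 1200.0
    distance_mm: float = 130.0
    # beam block
    focus_fwhm_nm: float = 200.0
    # numerics
    n_snapshots: int = 100
    snapshot_stride: int = 1
    emc_level: int = 2
    emc_max_iter: int = 40
    emc_tol: float = 1e-3
    # seeds
    master_seed: int = 1
    output_dir: str | None = None

    def __post_init__(self):
        for name in (
            "n_pulses",
            "n_trajectories_per_pulse",
            "n_patterns_per_trajectory",
            "n_emc_runs",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def n_damage_runs(self) -> int:
        return self.n_pulses * self.n_trajectories_per_pulse

    def geometry(self) -> dfr.DetectorGeometry:
        return dfr.DetectorGeometry(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            pixel_size_um=self.pixel_size_um,
            distance_mm=self.distance_mm,
            photon_energy_keV=self.photon_energy_keV,
        )

    def beam(self) -> pls.BeamConditions:
        return pls.BeamConditions(focus_fwhm=self.focus_fwhm_nm * 10.0)

    def structure(self) -> smp.AtomicStructure:
        if self.pdb_path:
            return smp.read_pdb(self.pdb_path)
        return smp.generate_pseudo_protein(
            self.fixture_n_atoms,
            self.fixture_radius_A,
            seed=stage_seed(self.master_seed, "structure"),
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=True)


def _manifest(config: RunConfig, extra: dict) -> dict:
    man = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_damage_runs": config.n_damage_runs,
        "n_patterns_total": config.n_damage_runs
        * config.n_patterns_per_trajectory,
        "focus_fwhm_nm": config.focus_fwhm_nm,
        "stage_seeds": {
            s: stage_seed(config.master_seed, s) for s in _STAGES
        },
    }
    man.update(extra)
    return man


def run_experiment(config: RunConfig, write: bool = True) -> dict:
    """Run the full ensemble experiment defined by ``config``.

    Returns a dict with the in-memory artefacts (pulses, trajectories,
    counts, quaternions, volumes, sigma_v report, run summary, manifest) and,
    when ``write`` and ``config.output_dir`` are set, writes the HDF5/CSV
    output tree plus a JSON manifest.
    """
    structure = config.structure()
    beam = config.beam()
    geometry = config.geometry()
    qmap = dfr.compute_qmap(geometry)

    pulses = [
        pls.generate_sase_pulse(
            config.fwhm_fs,
            config.photons_per_pulse,
            photon_energy=config.photon_energy_keV,
            coherence_time_fs=config.coherence_time_fs,
            n_samples=config.n_snapshots,
            seed=stage_seed(config.master_seed, "pulse", i),
        )
        for i in range(config.n_pulses)
    ]

    dparams = dmg.DamageParams(n_snapshots=config.n_snapshots)
    trajectories = []
    for ip, pulse in enumerate(pulses):
        for it in range(config.n_trajectories_per_pulse):
            idx = ip * config.n_trajectories_per_pulse + it
            trajectories.append(
                dmg.run_damage(
                    structure,
                    pulse,
                    beam,
                    params=dparams,
                    seed=stage_seed(config.master_seed, "damage", idx),
                )
            )

    counts = []
    expected_totals = []
    quats = []
    ipat = 0
    for ip, pulse in enumerate(pulses):
        for it in range(config.n_trajectories_per_pulse):
            traj = trajectories[ip * config.n_trajectories_per_pulse + it]
            for _ in range(config.n_patterns_per_trajectory):
                seed = stage_seed(config.master_seed, "pattern", ipat)
                rng = np.random.default_rng(seed)
                rot = smp.random_rotation(rng)
                pat = dfr.integrate_pattern(
                    traj, pulse, beam, qmap, rot,
                    snapshot_stride=config.snapshot_stride,
                )
                pat = dfr.poissonize(pat, seed=seed)
                counts.append(pat.counts)
                expected_totals.append(pat.total_expected)
                quats.append(rot.quaternion)
                ipat += 1
    counts = np.array(counts)
    quats = np.array(quats)

    operator = emc_mod.EMCOperator(geometry, level=config.emc_level)
    volumes = []
    emc_infos = []
    for k in range(config.n_emc_runs):
        vol, info = emc_mod.run_emc(
            counts,
            operator=operator,
            max_iter=config.emc_max_iter,
            tol=config.emc_tol,
            seed=stage_seed(config.master_seed, "emc", k),
        )
        volumes.append(vol)
        emc_infos.append(info)

    report = (
        met.coefficient_of_variation(volumes, align=True)
        if len(volumes) >= 2
        else None
    )
    summary = met.run_summary(pulses, trajectories, counts)

    escaped = float(np.mean([t.n_escaped[-1] for t in trajectories]))
    trapped = float(np.mean([t.n_free[-1] for t in trajectories]))
    manifest = _manifest(
        config,
        {
            "n_patterns_emitted": len(counts),
            "mean_escaped_electrons": escaped,
            "mean_trapped_electrons": trapped,
            "n_clamped_qvectors": operator.n_clamped,
            "emc_converged": [bool(i["converged"]) for i in emc_infos],
            "sigma_v_aligned": True,
        },
    )

    result = {
        "config": config,
        "structure": structure,
        "pulses": pulses,
        "trajectories": trajectories,
        "counts": counts,
        "quaternions": quats,
        "expected_totals": np.array(expected_totals),
        "volumes": volumes,
        "emc_infos": emc_infos,
        "report": report,
        "summary": summary,
        "manifest": manifest,
    }

    if write and config.output_dir:
        _write_outputs(result)
    return result


def _summary_frame(summaries: dict) -> pd.DataFrame:
    rows = []
    for label, s in summaries.items():
        rows.append(
            {
                "label": label,
                "N_ph_pulse": s.n_ph_pulse,
                "N_ph_det": s.n_ph_det,
                "efficiency": s.efficiency,
                "N_e_bound_mid": s.n_e_bound_mid,
                "N_e_bound_mid_sq": s.n_e_bound_mid_sq,
                "n_patterns": s.n_patterns,
            }
        )
    return pd.DataFrame(rows)


def _write_outputs(result: dict) -> None:
    config: RunConfig = result["config"]
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    pls.save_pulses(out / "pulses.h5", result["pulses"])
    import h5py

    with h5py.File(out / "trajectories.h5", "w") as f:
        for i, tr in enumerate(result["trajectories"]):
            g = f.create_group(f"traj_{i:05d}")
            g.create_dataset("positions", data=tr.positions)
            g.create_dataset("z_bound", data=tr.z_bound)
            g.create_dataset("n_free", data=tr.n_free)
            g.create_dataset("n_escaped", data=tr.n_escaped)
            g.create_dataset("snapshot_times", data=tr.snapshot_times)
            g.attrs["seed"] = tr.seed
            g.attrs["dt_fs"] = tr.dt

    dfr.save_patterns(
        out / "patterns.h5",
        result["counts"],
        result["quaternions"],
        config.geometry(),
    )
    for k, vol in enumerate(result["volumes"]):
        emc_mod.save_volume(out / f"volume_{k:02d}.h5", vol)

    if result["report"] is not None:
        frame = result["report"].to_frame()
        frame.to_csv(out / "sigma_v.csv", index=False, float_format="%.8g")
    _summary_frame({f"{config.fwhm_fs:g}fs": result["summary"]}).to_csv(
        out / "run_summary.csv", index=False, float_format="%.8g"
    )
    with open(out / "manifest.json", "w") as f:
        json.dump(result["manifest"], f, indent=2, sort_keys=True, default=str)


def compare_durations(results: dict, output_dir=None) -> dict:
    """Joint comparison of >= 2 completed experiments on one geometry.

    ``results`` maps a pulse duration (fs) to the dict from
    ``run_experiment``.  Emits the joint run-summary table, the sigma_v(q)
    curves per duration, and — for the shortest duration — the two
    rescaling variants (global mean-matching factor, and per-pattern
    mean+rms matching) against the next-shorter duration's statistics, each
    re-oriented with the same number of EMC runs.
    """
    if len(results) < 2:
        raise ValueError("need at least two completed experiments")
    durations = sorted(results)
    g0 = results[durations[0]]["config"].geometry()
    for d in durations[1:]:
        g = results[d]["config"].geometry()
        if (g.n_rows, g.n_cols, g.pixel_size_um, g.distance_mm) != (
            g0.n_rows,
            g0.n_cols,
            g0.pixel_size_um,
            g0.distance_mm,
        ):
            raise ValueError("geometry mismatch across experiments")

    summaries = {
        f"{d:g}fs": results[d]["summary"] for d in durations
    }
    curves = {f"{d:g}fs": results[d]["report"] for d in durations}

    short, ref = durations[0], durations[1]
    cfg = results[short]["config"]
    ref_totals = results[ref]["counts"].sum(axis=1)
    target_mean = float(ref_totals.mean())
    target_rms = float(ref_totals.std())

    operator = emc_mod.EMCOperator(g0, level=cfg.emc_level)
    variants = {}
    scaled_mean, factor = met.rescale_mean(results[short]["counts"], target_mean)
    scaled_both, _, n_dropped = met.rescale_mean_rms(
        results[short]["counts"], target_mean, target_rms
    )
    for name, data in (
        (f"{short:g}fs_rescaled_mean", scaled_mean),
        (f"{short:g}fs_rescaled_mean_rms", scaled_both),
    ):
        vols = [
            emc_mod.run_emc(
                data,
                operator=operator,
                max_iter=cfg.emc_max_iter,
                tol=cfg.emc_tol,
                seed=stage_seed(cfg.master_seed, "emc", 100 + k),
            )[0]
            for k in range(cfg.n_emc_runs)
        ]
        curves[name] = met.coefficient_of_variation(vols, align=True)
        variants[name] = curves[name]

    frames = []
    for label, rep in curves.items():
        fr = rep.to_frame()
        fr.insert(0, "label", label)
        frames.append(fr)
    sigma_frame = pd.concat(frames, ignore_index=True)
    summary_frame = _summary_frame(summaries)

    out = {
        "summaries": summaries,
        "curves": curves,
        "rescale_factor_mean": factor,
        "rescale_dropped": n_dropped,
        "sigma_v_frame": sigma_frame,
        "summary_frame": summary_frame,
    }
    if output_dir is not None:
        outp = Path(output_dir)
        outp.mkdir(parents=True, exist_ok=True)
        sigma_frame.to_csv(
            outp / "sigma_v_comparison.csv", index=False, float_format="%.8g"
        )
        summary_frame.to_csv(
            outp / "run_summary_comparison.csv", index=False, float_format="%.8g"
        )
    return out
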