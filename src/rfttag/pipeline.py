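"""Config-driven orchestration: simulate -> analyze -> stats -> report.

A :class:`RunConfig` fixes every parameter of a run — session type, gain
model overrides, layout size, analysis windows, permutation counts and the
master seed — and every stage derives its randomness deterministically from
that seed, so an identical config produces byte-identical outputs.

Stage outputs (all plain text except the epoch arrays):

* ``epochs/sub-XX.npz`` + JSON/TSV sidecars — simulated recordings,
* ``coherence.tsv`` — per participant x condition x combined sensor
  coherence in the stimulation and baseline intervals,
* ``participant_tests.tsv`` — the per-participant permutation criterion,
* ``cluster_tests.json`` — group-level cluster permutation results,
* ``summary.tsv`` / ``summary.json`` — per-condition grand averages,
  proportion significant, slopes, lateralization indices, and the
  frequency-separation / intermodulation design checks.
"""

from __future__ import annotations

import dataclasses
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design
from .spectral import (
    BASELINE_WINDOW_S,
    STIM_WINDOW_S,
    coherence_spectrum,
    combine_planar_pairs,
    trial_coefficients,
)
from .stats import (
    cluster_permutation_test,
    fit_condition_slope,
    lateralization_index,
    participant_permutation_test,
    proportion_significant,
)
from .stimulus import Condition, SessionType
from .synthmeg import (
    EpochSet,
    GainModel,
    SensorLayout,
    default_layout,
    simulate_conditions,
    simulate_study,
)

__all__ = ["RunConfig", "run_pipeline", "make_fixture", "FIXTURE_NAMES"]

#: Conditions excluded from analysis by default: 100 Hz is a harmonic of
#: the 50 Hz power-line frequency and is scheduled but never analysed.
DEFAULT_EXCLUDED_FREQS_HZ = (100.0,)


@dataclass
class RunConfig:
    """Full specification of a pipeline run."""

    session_type: str = "FREQ"
    master_seed: int = 0
    out_dir: str = "rft_out"
    # simulation size
    n_participants: int = 4
    n_trials_per_condition: int | None = 12
    n_posterior: int = 12
    n_other: int = 12
    gain_overrides: dict = field(default_factory=dict)
    # analysis
    sensor_type: str = "grad"
    baseline_window_s: tuple[float, float] = BASELINE_WINDOW_S
    stim_window_s: tuple[float, float] = STIM_WINDOW_S
    excluded_freqs_hz: tuple[float, ...] = DEFAULT_EXCLUDED_FREQS_HZ
    # statistics
    n_perm_cluster: int = 500
    n_perm_participant: int = 500
    alpha: float = 0.05
    cluster_alpha: float = 0.05
    sensor_set: list[str] | None = None   # raw channel ids; default: posterior grads

    _KNOWN = None  # populated below

    def __post_init__(self) -> None:
        SessionType(self.session_type)  # validate
        self.baseline_window_s = tuple(self.baseline_window_s)
        self.stim_window_s = tuple(self.stim_window_s)
        self.excluded_freqs_hz = tuple(self.excluded_freqs_hz)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("_KNOWN", None)
        d["baseline_window_s"] = list(self.baseline_window_s)
        d["stim_window_s"] = list(self.stim_window_s)
        d["excluded_freqs_hz"] = list(self.excluded_freqs_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls) if f.name != "_KNOWN"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"invalid config keys: {sorted(unknown)}; "
                             f"valid keys are {sorted(known)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    # -- derived objects ----------------------------------------------------
    def seeds(self) -> dict[str, int]:
        """Named sub-seeds derived deterministically from the master seed."""
        ss = np.random.SeedSequence(self.master_seed)
        names = ("layout", "simulate", "participant_test", "cluster_test")
        vals = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(len(names))]
        return dict(zip(names, vals))

    def gain_model(self) -> GainModel:
        return GainModel(**self.gain_overrides)

    def layout(self) -> SensorLayout:
        return default_layout(self.n_posterior, self.n_other,
                              seed=self.seeds()["layout"])

    def default_sensor_set(self, layout: SensorLayout) -> list[str]:
        """Selected posterior sensors: the layout's posterior channels of
        the analysis sensor type (stand-in for a by-inspection choice)."""
        if self.sensor_set is not None:
            return list(self.sensor_set)
        ch = layout.channels
        sel = ch[(ch["type"] == self.sensor_type) & ch["posterior"]]
        return list(sel["id"])


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: RunConfig, layout: SensorLayout) -> list[EpochSet]:
    return simulate_study(
        config.session_type,
        gain_model=config.gain_model(),
        layout=layout,
        n_participants=config.n_participants,
        n_trials_override=config.n_trials_per_condition,
        seed=config.seeds()["simulate"],
    )


def stage_analyze(config: RunConfig, epochsets: list[EpochSet],
                  layout: SensorLayout) -> dict[str, pd.DataFrame]:
    """Per-participant coherence and permutation criterion, per condition."""
    sensor_set = config.default_sensor_set(layout)
    seeds = np.random.SeedSequence(config.seeds()["participant_test"])
    part_rngs = [np.random.default_rng(c) for c in seeds.spawn(len(epochsets))]

    coh_rows: list[dict] = []
    test_rows: list[dict] = []
    for ep, rng in zip(epochsets, part_rngs):
        ep = ep.tagging_trials()
        base = trial_coefficients(ep, config.baseline_window_s)
        stim = trial_coefficients(ep, config.stim_window_s)
        info = ep.trial_info
        for cond_id, sub in info.groupby("condition_id", sort=True):
            freq = float(sub["freq_hz"].iloc[0])
            if freq in config.excluded_freqs_hz:
                continue
            mask = (info["condition_id"] == cond_id).to_numpy()
            est_s = combine_planar_pairs(
                coherence_spectrum(stim.select_trials(mask)), layout)
            est_b = combine_planar_pairs(
                coherence_spectrum(base.select_trials(mask)), layout)
            coh_s = est_s.coherence_at(freq)
            coh_b = est_b.coherence_at(freq)
            for sid, cs, cb in zip(est_s.sensor_ids, coh_s, coh_b):
                coh_rows.append(dict(
                    participant=ep.participant_id, condition_id=cond_id,
                    freq_hz=freq, size_deg=float(sub["size_deg"].iloc[0]),
                    pos_x_deg=float(sub["pos_x_deg"].iloc[0]),
                    pos_y_deg=float(sub["pos_y_deg"].iloc[0]),
                    sensor=sid, coh_stim=cs, coh_base=cb))
            res = participant_permutation_test(
                base.select_trials(mask), stim.select_trials(mask),
                sensor_set, freq, n_perm=config.n_perm_participant, seed=rng)
            test_rows.append(dict(
                participant=ep.participant_id, condition_id=cond_id,
                freq_hz=freq, observed=res.observed,
                baseline_observed=res.baseline_observed,
                null_q95=res.null_quantile_95, p_value=res.p_value,
                significant=res.significant))
    return {"coherence": pd.DataFrame(coh_rows),
            "participant_tests": pd.DataFrame(test_rows)}


def _pair_sensor_matrices(coh: pd.DataFrame, layout: SensorLayout,
                          cond_id: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Participants x combined-gradiometer matrices for one condition."""
    pair_ids = [f"P{p:02d}" for p in range(layout.n_positions)]
    sub = coh[(coh["condition_id"] == cond_id) & coh["sensor"].isin(pair_ids)]
    stim = sub.pivot(index="participant", columns="sensor", values="coh_stim")
    base = sub.pivot(index="participant", columns="sensor", values="coh_base")
    stim = stim.reindex(columns=pair_ids)
    base = base.reindex(columns=pair_ids)
    return stim.to_numpy(), base.to_numpy(), pair_ids


def stage_stats(config: RunConfig, analysis: dict[str, pd.DataFrame],
                layout: SensorLayout) -> dict:
    """Group-level cluster permutation test per condition (stim vs base)."""
    coh = analysis["coherence"]
    rng = np.random.default_rng(config.seeds()["cluster_test"])
    out: dict[str, dict] = {}
    for cond_id in sorted(coh["condition_id"].unique()):
        stim, base, pair_ids = _pair_sensor_matrices(coh, layout, cond_id)
        res = cluster_permutation_test(
            stim, base, layout.adjacency, n_perm=config.n_perm_cluster,
            alpha=config.alpha, cluster_alpha=config.cluster_alpha, seed=rng)
        out[cond_id] = {
            "n_permutations": res.n_permutations,
            "enumerated": res.enumerated,
            "clusters": [
                {"sensors": [pair_ids[i] for i in c.sensors],
                 "mass": c.mass, "p_value": c.p_value,
                 "significant": c.p_value < config.alpha}
                for c in res.clusters],
        }
    return out


def _posterior_pair_ids(layout: SensorLayout) -> list[str]:
    return [f"P{p:02d}" for p in layout.posterior_positions()]


def stage_report(config: RunConfig, analysis: dict[str, pd.DataFrame],
                 cluster_results: dict, layout: SensorLayout) -> dict:
    """Condition summary, slopes, lateralization and design checks."""
    coh = analysis["coherence"]
    tests = analysis["participant_tests"]
    post = _posterior_pair_ids(layout)

    rows = []
    for cond_id, sub in coh[coh["sensor"].isin(post)].groupby("condition_id", sort=True):
        per_part = sub.groupby("participant")[["coh_stim", "coh_base"]].mean()
        tsub = tests[tests["condition_id"] == cond_id]
        clus = cluster_results.get(cond_id, {"clusters": []})["clusters"]
        rows.append(dict(
            condition_id=cond_id,
            freq_hz=float(sub["freq_hz"].iloc[0]),
            size_deg=float(sub["size_deg"].iloc[0]),
            pos_x_deg=float(sub["pos_x_deg"].iloc[0]),
            pos_y_deg=float(sub["pos_y_deg"].iloc[0]),
            mean_coh_stim=float(per_part["coh_stim"].mean()),
            mean_coh_base=float(per_part["coh_base"].mean()),
            sem_coh_stim=float(per_part["coh_stim"].sem()) if len(per_part) > 1 else 0.0,
            pct_participants_significant=proportion_significant(
                tsub["significant"].tolist()),
            n_significant_clusters=sum(c["significant"] for c in clus),
            min_cluster_p=min((c["p_value"] for c in clus), default=float("nan")),
        ))
    summary = pd.DataFrame(rows).sort_values("condition_id").reset_index(drop=True)

    extras: dict = {
        "design_checks": {
            "min_separation_hz_window_0.2s": design.min_tag_separation_hz(0.2),
            "min_separation_hz_window_0.5s": design.min_tag_separation_hz(0.5),
            "intermodulation_55_60_hz": design.intermodulation_freqs(55.0, 60.0),
        }
    }
    session = SessionType(config.session_type)
    if session == SessionType.FREQ and len(summary) >= 3:
        slope, se = fit_condition_slope(summary["freq_hz"] / 4.0,
                                        summary["mean_coh_stim"])
        extras["slope_coherence_per_4hz"] = {"slope": slope, "stderr": se}
    if session == SessionType.SIZE and len(summary) >= 3:
        slope, se = fit_condition_slope(summary["size_deg"],
                                        summary["mean_coh_stim"])
        extras["slope_coherence_per_degree"] = {"slope": slope, "stderr": se}
    if session == SessionType.POSITION:
        lis = []
        for _, row in summary[summary["pos_x_deg"] < 0].iterrows():
            mirror = summary[(summary["pos_x_deg"] == -row["pos_x_deg"])
                             & (summary["pos_y_deg"] == row["pos_y_deg"])]
            if len(mirror) == 1:
                li = lateralization_index(row["mean_coh_stim"],
                                          float(mirror["mean_coh_stim"].iloc[0]),
                                          tag_freq_hz=row["freq_hz"])
                lis.append(dict(left_condition=row["condition_id"],
                                right_condition=str(mirror["condition_id"].iloc[0]),
                                pos_y_deg=row["pos_y_deg"], li=li.li))
        extras["lateralization"] = lis
    return {"summary": summary, "extras": extras}


def run_pipeline(config: RunConfig, write_epochs: bool = False) -> dict:
    """Run all stages and write the report bundle to ``config.out_dir``.

    Returns a dict with the layout, analysis tables, cluster results and
    summary.  On failure partial outputs are removed.
    """
    out = Path(config.out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    try:
        config.to_yaml(out / "config.yaml")
        layout = config.layout()
        layout.to_csv(out / "layout.csv")
        epochsets = stage_simulate(config, layout)
        if write_epochs:
            (out / "epochs").mkdir(exist_ok=True)
            for ep in epochsets:
                ep.save(out / "epochs" / f"{ep.participant_id}.npz")
        analysis = stage_analyze(config, epochsets, layout)
        analysis["coherence"].to_csv(out / "coherence.tsv", sep="\t",
                                     index=False, float_format="%.8g")
        analysis["participant_tests"].to_csv(out / "participant_tests.tsv",
                                             sep="\t", index=False,
                                             float_format="%.8g")
        clusters = stage_stats(config, analysis, layout)
        (out / "cluster_tests.json").write_text(json.dumps(clusters, indent=2))
        report = stage_report(config, analysis, clusters, layout)
        report["summary"].to_csv(out / "summary.tsv", sep="\t", index=False,
                                 float_format="%.8g")
        (out / "summary.json").write_text(json.dumps(
            {"summary": report["summary"].to_dict(orient="records"),
             **report["extras"]}, indent=2))
    except Exception:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise
    return {"layout": layout, "epochs": epochsets, "analysis": analysis,
            "cluster_tests": clusters, **report}


# ---------------------------------------------------------------------------
# fixtures

FIXTURE_NAMES = ("null", "strong-tag", "freq-sweep-mini", "position-mini")


def make_fixture(name: str, seed: int = 0) -> dict:
    """Small bundled datasets for tests and demos (seconds to generate).

    * ``null`` — zero tagging gain, noise-only sensors.
    * ``strong-tag`` — high-gain, low-jitter 60 Hz tagging; every simulated
      participant passes the permutation criterion.
    * ``freq-sweep-mini`` — 3 frequencies (60/76/92 Hz) x 12 trials.
    * ``position-mini`` — 4 grid positions x 12 trials at 66 Hz.
    """
    layout = default_layout(8, 4, seed=seed)
    if name == "null":
        gm = GainModel().null()
        conds = [Condition(freq_hz=60.0)]
        eps = simulate_conditions(conds, 10, gm, layout, n_participants=3, seed=seed)
    elif name == "strong-tag":
        gm = dataclasses.replace(GainModel(), amp0=6.0, phase_jitter_sd=0.0,
                                 participant_sigma=0.0)
        conds = [Condition(freq_hz=60.0)]
        eps = simulate_conditions(conds, 10, gm, layout, n_participants=3, seed=seed)
    elif name == "freq-sweep-mini":
        gm = GainModel()
        conds = [Condition(freq_hz=f) for f in (60.0, 76.0, 92.0)]
        eps = simulate_conditions(conds, 12, gm, layout, n_participants=2, seed=seed)
    elif name == "position-mini":
        gm = GainModel()
        conds = [Condition(freq_hz=66.0, position_deg=p)
                 for p in ((-6.0, -6.0), (6.0, -6.0), (0.0, -6.0), (0.0, 6.0))]
        eps = simulate_conditions(conds, 12, gm, layout, n_participants=2, seed=seed)
    else:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return {"name": name, "epochs": eps, "layout": layout, "gain_model": gm,
            "seed": seed}
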