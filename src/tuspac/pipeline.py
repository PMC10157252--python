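"""Orchestration: simulate -> analyze -> compare, plus the dose-response sweep.

A full experiment mirrors the in-vivo design: three behavioral states
(anesthesia, awake, running), N = 7 animals per state, 16 stimulation
trials per animal. Each animal is one synthetic session; per-session
analysis produces the peristimulus band-power table and per-trial PAC
estimates; per-animal summaries then enter the Kruskal-Wallis state
comparison. The dose-response sweep repeats the cohort at the five
stimulation pressures (0.15-0.75 MPa) and summarises each state's trend
with a Spearman rank correlation across intensities.

All outputs embed the master seed and a hash of the configuration;
re-running with an identical config reproduces the tables bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats

from . import io as tio
from .pac import session_pac, pac_change
from .spectral import (
    DEFAULT_WELCH,
    GAMMA,
    THETA,
    WelchParams,
    band_power_table,
)
from .stats import compare_states
from .stimulus import StimulusProtocol, pressure_to_isppa
from .synthetic import STATE_LABELS, StateProfile, generate_session, state_profile

__all__ = [
    "RunConfig",
    "simulate_cohort",
    "analyze_session",
    "cohort_tables",
    "state_comparisons",
    "run_experiment",
    "dose_response_sweep",
    "DEFAULT_SWEEP_PRESSURES",
]

DEFAULT_SWEEP_PRESSURES = (0.15, 0.30, 0.45, 0.60, 0.75)

#: Post-onset 1-s segments carrying the stimulus effect, for sweep summaries.
EFFECT_SEGMENTS = (0, 1)


@dataclass
class RunConfig:
    """Configuration of one experiment run."""

    seed: int = 0
    n_animals: int = 7
    states: tuple = STATE_LABELS
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    profile_overrides: dict = field(default_factory=dict)
    welch: WelchParams = field(default_factory=WelchParams)
    pre_window: tuple = (-2.0, 0.0)
    post_window: tuple = (0.0, 2.0)
    posthoc_method: str = "dunn-holm"
    pressures: tuple = DEFAULT_SWEEP_PRESSURES
    output_dir: Optional[str] = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "protocol" in d:
            d["protocol"] = StimulusProtocol.from_dict(d["protocol"])
        if "welch" in d:
            d["welch"] = WelchParams(**d["welch"])
        for key in ("states", "pressures", "pre_window", "post_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(tio.load_config(path) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["protocol"] = self.protocol.to_dict()
        return d

    @property
    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def profile(self, state: str) -> StateProfile:
        return state_profile(state, **self.profile_overrides.get(state, {}))


def _animal_seed(master: int, state_index: int, animal: int) -> int:
    """Deterministic per-animal seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master), state_index, animal])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cohort(config: RunConfig, pressure_mpa: Optional[float] = None):
    """Simulate one session per (state, animal); returns {state: [sessions]}."""
    protocol = config.protocol
    if pressure_mpa is not None:
        protocol = StimulusProtocol.from_dict(
            {**protocol.to_dict(), "pressure_mpa": pressure_mpa}
        )
    cohort = {}
    for si, state in enumerate(config.states):
        profile = config.profile(state)
        cohort[state] = [
            generate_session(
                profile,
                protocol,
                seed=_animal_seed(config.seed, si, animal),
            )
            for animal in range(config.n_animals)
        ]
    return cohort


def analyze_session(session, config: RunConfig = None):
    """Per-session analysis: band-power table and per-trial PAC estimates.

    Returns (power_df, pac_summary) where pac_summary holds the per-trial
    pre/post PACI values, the trial-pooled pre/post PACI (the per-animal
    statistic), and the per-animal dPAC/PAC = post/pre - 1 of the pooled
    estimates.
    """
    config = config or RunConfig()
    power = band_power_table(
        session, bands=(THETA, GAMMA), welch=config.welch
    )
    pre, post, pooled = session_pac(
        session,
        pre_window=config.pre_window,
        post_window=config.post_window,
    )
    pac_summary = {
        "pre_trial_paci": np.array([e.paci for e in pre]),
        "post_trial_paci": np.array([e.paci for e in post]),
        "pre_paci": pooled["pre"].paci,
        "post_paci": pooled["post"].paci,
        "dpac_over_pac": pac_change(pooled["pre"], pooled["post"]),
        "k": pooled["pre"].k,
        "edge_trim_s": pooled["pre"].edge_trim_s,
    }
    return power, pac_summary


def cohort_tables(cohort: dict, config: RunConfig = None):
    """Tidy power and PAC tables for a simulated or loaded cohort.

    Returns (power_table, pac_table); power_table has one row per
    (state, animal, band, segment), pac_table one row per (state, animal).
    """
    config = config or RunConfig()
    power_rows, pac_rows = [], []
    for state, sessions in cohort.items():
        for animal, session in enumerate(sessions):
            power, pac = analyze_session(session, config)
            power.insert(0, "animal", animal)
            power.insert(0, "state", state)
            power_rows.append(power)
            pac_rows.append(
                {
                    "state": state,
                    "animal": animal,
                    "paci_pre": pac["pre_paci"],
                    "paci_post": pac["post_paci"],
                    "dpac_over_pac": pac["dpac_over_pac"],
                    "k": pac["k"],
                    "trim_s": pac["edge_trim_s"],
                }
            )
    return pd.concat(power_rows, ignore_index=True), pd.DataFrame(pac_rows)


def _metric_by_state(power_table, band, segment_start, column):
    """{state: per-animal values} for one band/segment metric."""
    sel = power_table[
        (power_table["band"] == band)
        & (power_table["segment_start_s"] == segment_start)
    ]
    return {
        state: grp.sort_values("animal")[column].to_numpy()
        for state, grp in sel.groupby("state", sort=False)
    }


def state_comparisons(power_table, pac_table, config: RunConfig = None):
    """Kruskal-Wallis state comparisons of the headline metrics.

    Compared metrics: dAP/AP of theta and gamma in the 0-1 s and 1-2 s
    post-onset bins, and dPAC/PAC. Returns a tidy DataFrame with one row
    per (metric, pair).
    """
    config = config or RunConfig()
    rows = []

    def add(metric_name, groups):
        comparison = compare_states(groups, method=config.posthoc_method)
        for _, pair in comparison.pairwise.iterrows():
            rows.append(
                {
                    "comparison": metric_name,
                    "H": comparison.h,
                    "df": comparison.df,
                    "p": comparison.p_value,
                    "pair": pair["pair"],
                    "p_adj": pair["p_adj"],
                    "stars": pair["stars"],
                }
            )

    for band in ("theta", "gamma"):
        for seg in (0, 1):
            add(
                f"dap_over_ap_{band}_{seg}to{seg + 1}s",
                _metric_by_state(power_table, band, seg, "dap_over_ap"),
            )
    add(
        "dpac_over_pac",
        {
            state: grp.sort_values("animal")["dpac_over_pac"].to_numpy()
            for state, grp in pac_table.groupby("state", sort=False)
        },
    )
    return pd.DataFrame(rows)


def run_experiment(config: RunConfig, output_dir=None):
    """Simulate, analyze, and compare a full cohort; optionally write tables.

    Writes power_table.tsv, pac_table.tsv, stats_report.tsv, and
    summary.json (config hash, seed, dose metadata) when an output
    directory is given; partially written outputs are removed on failure.
    Returns {"power": ..., "pac": ..., "stats": ..., "summary": ...}.
    """
    cohort = simulate_cohort(config)
    power_table, pac_table = cohort_tables(cohort, config)
    stats_report = state_comparisons(power_table, pac_table, config)
    summary = {
        "seed": config.seed,
        "config_hash": config.config_hash,
        "n_animals": config.n_animals,
        "states": list(config.states),
        "pressure_mpa": config.protocol.peak_pressure,
        "isppa_w_cm2": pressure_to_isppa(config.protocol.peak_pressure),
    }
    results = {
        "power": power_table,
        "pac": pac_table,
        "stats": stats_report,
        "summary": summary,
    }
    outdir = output_dir or config.output_dir
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        try:
            for name, table in (
                ("power_table.tsv", power_table),
                ("pac_table.tsv", pac_table),
                ("stats_report.tsv", stats_report),
            ):
                path = outdir / name
                table.to_csv(path, sep="\t", index=False)
                written.append(path)
            path = outdir / "summary.json"
            path.write_text(json.dumps(summary, indent=2, sort_keys=True))
            written.append(path)
        except Exception:
            for path in written:
                path.unlink(missing_ok=True)
            raise
    return results


def write_cohort(cohort: dict, outdir, fmt: str = "csv") -> None:
    """Write each simulated session (samples, events, provenance sidecar)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for state, sessions in cohort.items():
        for animal, session in enumerate(sessions):
            stem = f"{state}_animal{animal:02d}"
            tio.write_lfp(outdir / f"{stem}.{fmt}", session, format=fmt)
            tio.write_events(
                outdir / f"{stem}_events.tsv", session.stimulus_onsets
            )
            (outdir / f"{stem}.json").write_text(
                json.dumps(session.provenance, indent=2, sort_keys=True,
                           default=str)
            )


def dose_response_sweep(
    config: RunConfig,
    pressures: Optional[Sequence[float]] = None,
):
    """Repeat the cohort across stimulation pressures and rank the trends.

    For each (state, pressure) the group means of the post-stimulus (0-2 s)
    theta and gamma relative power and of dPAC/PAC are computed; per state
    and metric a Spearman rank correlation across the pressure levels
    summarises the monotone trend.

    Returns (curves, spearman): curves has one row per (state, pressure),
    spearman one row per (state, metric).
    """
    pressures = tuple(pressures if pressures is not None else config.pressures)
    if len(pressures) < 3:
        raise ValueError("need at least three pressure levels")
    if len(set(pressures)) != len(pressures):
        raise ValueError("duplicate pressure levels in sweep")
    rows = []
    for pressure in pressures:
        cohort = simulate_cohort(config, pressure_mpa=pressure)
        power_table, pac_table = cohort_tables(cohort, config)
        for state in config.states:
            sel = power_table[power_table["state"] == state]
            post = sel[sel["segment_start_s"].isin(EFFECT_SEGMENTS)]
            theta_rp = post[post["band"] == "theta"]["rp"].mean()
            gamma_rp = post[post["band"] == "gamma"]["rp"].mean()
            dpac = pac_table[pac_table["state"] == state][
                "dpac_over_pac"
            ].mean()
            rows.append(
                {
                    "state": state,
                    "pressure_mpa": pressure,
                    "isppa_w_cm2": pressure_to_isppa(pressure),
                    "theta_rp_post": theta_rp,
                    "gamma_rp_post": gamma_rp,
                    "dpac_over_pac": dpac,
                }
            )
    curves = pd.DataFrame(rows)
    spearman_rows = []
    for state in config.states:
        sub = curves[curves["state"] == state].sort_values("pressure_mpa")
        for metric in ("theta_rp_post", "gamma_rp_post", "dpac_over_pac"):
            values = sub[metric].to_numpy()
            if np.ptp(values) == 0:  # flat curve carries no trend
                rho = 0.0
            else:
                rho = float(
                    spstats.spearmanr(sub["pressure_mpa"], values).statistic
                )
            spearman_rows.append(
                {"state": state, "metric": metric, "spearman_rho": rho}
            )
    return curves, pd.DataFrame(spearman_rows)


def render_figures(results: dict, outdir) -> list:
    """Optional summary figures (band-power and dPAC/PAC bars) as PNGs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    power, pac = results["power"], results["pac"]
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=False)
    for ax, band in zip(axes, ("theta", "gamma")):
        for state, grp in power[power["band"] == band].groupby("state"):
            mean = grp.groupby("segment_start_s")["ap"].mean()
            ax.plot(mean.index + 0.5, mean.values, marker="o", label=state)
        ax.axvspan(0, 2, color="0.85")
        ax.set_xlabel("time from onset (s)")
        ax.set_ylabel(f"{band} AP (mV$^2$/Hz)")
        ax.set_yscale("log")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    path = outdir / "band_power.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    paths.append(path)

    fig, ax = plt.subplots(figsize=(4, 3.5))
    summary = pac.groupby("state")["dpac_over_pac"].agg(["mean", "sem"])
    ax.bar(summary.index, summary["mean"], yerr=summary["sem"], color="0.6")
    ax.axhline(0, color="k", lw=0.8)
    ax.set_ylabel(r"$\Delta$PAC/PAC")
    fig.tight_layout()
    path = outdir / "pac_change.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    paths.append(path)
    return paths
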