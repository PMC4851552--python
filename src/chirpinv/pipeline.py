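"""End-to-end, seeded analysis pipeline.

Runs stimulus synthesis, per-stage spike-train simulation, PSTH / rho(t)
computation, response measures, tuning curves, and invariance scores at all
levels, plus the behavioral echo-response branch, from a single serializable
configuration.  Every random choice derives from the run seed through
spawned child streams, so a run is reproducible bit-for-bit from its config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from chirpinv import behavior as bhv
from chirpinv import invariance as inv
from chirpinv import spiketrain as spk
from chirpinv import synthetic_data as syn
from chirpinv.stimulus import AMWaveform, BeatSpec, ChirpSpec, make_waveform_set

logger = logging.getLogger("chirpinv")

__all__ = [
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
    "summarize",
    "stimulus_windows",
    "afferent_response_traces",
    "pyramidal_response_traces",
    "ts_response_traces",
    "pair_correlation_traces",
    "behavioral_experiment",
]


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    # stimulus
    f_beat: float = 4.0
    duration: float = 2.0
    sample_rate: float = 10_000.0
    delta_f: float = 60.0
    sigma: float = 0.014
    chirp_onset_time: float = 1.0
    # populations (defaults follow the reference sample sizes:
    # 18 single afferents, 8 pairs, 22 ON + 9 OFF pyramidal cells,
    # 25 TS neurons, 29 fish)
    n_afferents: int = 18
    n_pairs: int = 8
    n_ell_on: int = 22
    n_ell_off: int = 9
    n_ts: int = 25
    n_fish: int = 29
    n_trials: int = 20
    jitter_baselines: bool = True
    # analysis options
    distance_convention: str = "rms"
    log_base: str = "e"
    chirp_window: float = 0.030
    corr_window: float = 0.03125
    corr_step: float = 0.00025
    psth_binwidth: float = 0.0001
    psth_smooth: float = 0.006
    rate_floor: float = 0.1
    ts_high_invariance_threshold: float = 0.25
    # behavior
    p_echo: float = 0.4
    behavior_psth_binwidth: float = 0.002
    n_boot: int = 200
    # bookkeeping
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - valid)
        if unknown:
            raise ValueError(f"invalid config keys: {unknown}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        import hashlib

        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def beat_spec(self) -> BeatSpec:
        return BeatSpec(f_beat=self.f_beat, duration=self.duration, sample_rate=self.sample_rate)

    def chirp_template(self) -> ChirpSpec:
        return ChirpSpec(delta_f=self.delta_f, sigma=self.sigma, onset_phase=0.0)


@dataclass
class PipelineResult:
    """All tables and traces produced by one run."""

    config: RunConfig
    waves: list[AMWaveform]
    invariance: pd.DataFrame  # unit_id, stage, subset, level, invariance
    responses: pd.DataFrame  # unit_id, stage, waveform_label, phase_deg, response
    signs: dict[str, str]
    tuning: dict[str, inv.TuningCurve]
    behavior_stats: pd.DataFrame | None = None
    summary: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Stage helpers (used by the pipeline, the acceptance script, and tests)


def stimulus_windows(waves: list[AMWaveform], window: float = 0.030) -> dict[str, np.ndarray]:
    """Chirp-window samples of each waveform, keyed by label."""
    return {w.label: w.chirp_window(window) for w in waves}


def _psth_windows_and_responses(
    trial_sets: dict[str, list[np.ndarray]],
    waves: list[AMWaveform],
    stage: str,
    config: RunConfig,
) -> tuple[dict[str, np.ndarray], dict[str, inv.ResponseValue], dict[str, spk.PSTH]]:
    """PSTH chirp-window traces and response measures for one unit."""
    windows: dict[str, np.ndarray] = {}
    responses: dict[str, inv.ResponseValue] = {}
    psths: dict[str, spk.PSTH] = {}
    for w in waves:
        psth = spk.compute_psth(
            trial_sets[w.label], w.duration, config.psth_binwidth, config.psth_smooth
        )
        psths[w.label] = psth
        windows[w.label] = psth.window(w.chirp_onset_time, config.chirp_window)
        responses[w.label] = inv.response_measure(
            psth,
            w.chirp_onset_time,
            stage=stage,
            rate_floor=config.rate_floor,
            log_base=config.log_base,
            label=w.label,
        )
    return windows, responses, psths


def afferent_response_traces(
    model: syn.NeuronModel,
    waves: list[AMWaveform],
    n_trials: int,
    seed,
    config: RunConfig | None = None,
):
    """Simulate one afferent on all waveforms; PSTH windows + responses."""
    config = config or RunConfig()
    ss = syn.as_seedseq(seed)
    seeds = ss.spawn(len(waves))
    trial_sets = {
        w.label: syn.simulate_afferent_trials(model, w, n_trials, s).trials("aff0", w.label)
        for w, s in zip(waves, seeds)
    }
    return _psth_windows_and_responses(trial_sets, waves, "afferent", config)


def pyramidal_response_traces(
    model: syn.NeuronModel,
    waves: list[AMWaveform],
    n_trials: int,
    seed,
    config: RunConfig | None = None,
):
    """Simulate one ON/OFF pyramidal cell on all waveforms."""
    config = config or RunConfig()
    ss = syn.as_seedseq(seed)
    seeds = ss.spawn(len(waves))
    trial_sets = {
        w.label: syn.simulate_pyramidal_trials(model, w, n_trials, s).trials("ell0", w.label)
        for w, s in zip(waves, seeds)
    }
    return _psth_windows_and_responses(trial_sets, waves, model.stage, config)


def ts_response_traces(
    model: syn.NeuronModel,
    waves: list[AMWaveform],
    n_trials: int,
    seed,
    config: RunConfig | None = None,
):
    """Simulate one TS neuron driven by the canonical ON/OFF rate traces."""
    config = config or RunConfig()
    on_model = syn.NeuronModel.default("ELL_ON")
    off_model = syn.NeuronModel.default("ELL_OFF")
    ss = syn.as_seedseq(seed)
    seeds = ss.spawn(len(waves))
    trial_sets = {}
    for w, s in zip(waves, seeds):
        on_drive = syn.pyramidal_rate(on_model, w)
        off_drive = syn.pyramidal_rate(off_model, w)
        sts = syn.simulate_ts_trials(
            on_drive,
            off_drive,
            model,
            n_trials,
            s,
            sample_rate=w.sample_rate,
            label=w.label,
            on_baseline=on_model.baseline_rate,
            off_baseline=off_model.baseline_rate,
        )
        trial_sets[w.label] = sts.trials("ts0", w.label)
    return _psth_windows_and_responses(trial_sets, waves, "TS", config)


def pair_correlation_traces(
    model_i: syn.NeuronModel,
    model_j: syn.NeuronModel,
    waves: list[AMWaveform],
    n_trials: int,
    seed,
    config: RunConfig | None = None,
    pairing: str = "simultaneous",
) -> dict[str, np.ndarray]:
    """rho(t) chirp-window traces for one afferent pair on all waveforms."""
    config = config or RunConfig()
    ss = syn.as_seedseq(seed)
    seeds = ss.spawn(len(waves))
    windows: dict[str, np.ndarray] = {}
    for w, s in zip(waves, seeds):
        set_i, set_j = syn.simulate_afferent_pair(model_i, model_j, w, n_trials, s)
        trace = spk.sliding_correlation(
            set_i.trials("aff_i", w.label),
            set_j.trials("aff_j", w.label),
            w.duration,
            window=config.corr_window,
            step=config.corr_step,
            pairing=pairing,
        )
        windows[w.label] = trace.window_values(w.chirp_onset_time, config.chirp_window)
    return windows


def behavioral_experiment(
    config: RunConfig, seed
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Simulate the echo-response experiment across fish and analyze it.

    Returns the per-phase behavioral PSTH traces (labelled S1..S8 to align
    with the stimulus set) and a per-presentation table of echo
    statistics.  Unlike neural responses, echo responses unfold over
    seconds (latencies up to 1 s), so the full PSTH time course over the
    analysis span is used as the response input to the invariance score;
    restricting a 1 s boxcar-smoothed trace to the 30 ms chirp window
    would leave only noise.
    """
    protocol = syn.EchoProtocol()
    ss = syn.as_seedseq(seed)
    fish_seeds = ss.spawn(config.n_fish)
    phase_to_label = {p: f"S{i + 1}" for i, p in enumerate(protocol.phases)}
    pooled: dict[str, list[float]] = {lab: [] for lab in phase_to_label.values()}
    presentations: dict[str, int] = {lab: 0 for lab in phase_to_label.values()}
    rows = []
    for fish_idx, fseed in enumerate(fish_seeds):
        trace = syn.simulate_echo_experiment(protocol, config.p_echo, seed=fseed)
        freq = bhv.FrequencyTrace(trace.eod_frequency, trace.sample_rate)
        first_onset = trace.stimulus_onsets[0]
        events = bhv.detect_chirps(
            freq, baseline_window=(first_onset - protocol.pre_record, first_onset)
        )
        for k, (onset, phase) in enumerate(
            zip(trace.stimulus_onsets, trace.stimulus_phases)
        ):
            stats = bhv.echo_metrics(events, onset, trace.times[-1])
            label = phase_to_label[float(phase)]
            presentations[label] += 1
            for ev in events:
                rel = ev.time - onset
                if -protocol.pre_record <= rel <= 2.0:
                    pooled[label].append(rel)
            rows.append(
                {
                    "fish_id": f"fish{fish_idx}",
                    "stimulus_index": k,
                    "phase_deg": float(phase),
                    "waveform_label": label,
                    "cr_chirp": stats.cr_chirp,
                    "cr_beat": stats.cr_beat,
                    "latency_s": stats.latency,
                    "behavior_response": stats.behavior_response,
                }
            )
    windows: dict[str, np.ndarray] = {}
    for label, times in pooled.items():
        _, rate = bhv.behavioral_psth(
            np.asarray(times),
            presentations[label],
            binwidth=config.behavior_psth_binwidth,
        )
        windows[label] = rate
    return windows, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full pipeline


def _unit_scores(
    resp_windows: dict[str, np.ndarray],
    stim_windows: dict[str, np.ndarray],
    signs: dict[str, str] | None,
    config: RunConfig,
    level: str,
) -> dict[str, float]:
    """Invariance for all pair subsets of one unit's response traces."""
    out = {}
    subsets = ["all"] if signs is None else ["all", "++/--", "+-"]
    for subset in subsets:
        score = inv.invariance_score(
            resp_windows,
            stim_windows,
            subset=subset,
            signs=signs,
            convention=config.distance_convention,
            level=level,
        )
        out[subset] = score.value
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full stimulus -> simulation -> analysis -> summary pipeline."""
    rng_root = np.random.SeedSequence(config.seed)
    (
        seed_aff,
        seed_pairs,
        seed_ell,
        seed_ts,
        seed_behavior,
        seed_pop,
        seed_boot,
    ) = rng_root.spawn(7)
    waves = make_waveform_set(
        config.beat_spec(), config.chirp_template(), config.chirp_onset_time
    )
    stim = stimulus_windows(waves, config.chirp_window)
    inv_rows: list[dict] = []
    resp_rows: list[dict] = []
    phase_of = {w.label: w.onset_phase for w in waves}

    # --- single afferents --------------------------------------------------
    logger.info("simulating %d single afferents", config.n_afferents)
    aff_models = syn.make_population(
        "afferent", config.n_afferents, seed_pop, jitter=config.jitter_baselines
    )
    aff_windows: list[dict[str, np.ndarray]] = []
    aff_responses: list[dict[str, inv.ResponseValue]] = []
    for u, (model, s) in enumerate(zip(aff_models, seed_aff.spawn(config.n_afferents))):
        win, resp, _ = afferent_response_traces(model, waves, config.n_trials, s, config)
        aff_windows.append(win)
        aff_responses.append(resp)
        for label, rv in resp.items():
            resp_rows.append(
                {
                    "unit_id": f"aff{u}",
                    "stage": "afferent",
                    "waveform_label": label,
                    "phase_deg": phase_of[label],
                    "response": rv.value,
                }
            )

    # '+'/'-' classification from the population-mean afferent responses
    pop_mean_resp = {
        label: float(np.mean([r[label].value for r in aff_responses]))
        for label in stim
    }
    signs = inv.classify_chirp_sign(pop_mean_resp)
    logger.info("chirp signs: %s", signs)

    for u, win in enumerate(aff_windows):
        for subset, value in _unit_scores(win, stim, signs, config, "single_unit").items():
            inv_rows.append(
                {
                    "unit_id": f"aff{u}",
                    "stage": "afferent",
                    "subset": subset,
                    "level": "single_unit",
                    "invariance": value,
                }
            )
    # population level: summed PSTHs
    pop_windows = {
        label: np.sum([win[label] for win in aff_windows], axis=0) for label in stim
    }
    for subset, value in _unit_scores(pop_windows, stim, signs, config, "population").items():
        inv_rows.append(
            {
                "unit_id": "afferent_population",
                "stage": "afferent",
                "subset": subset,
                "level": "population",
                "invariance": value,
            }
        )

    # --- afferent pairs: correlated activity -------------------------------
    logger.info("simulating %d afferent pairs", config.n_pairs)
    pair_models = syn.make_population(
        "afferent", 2 * config.n_pairs, seed_pop.spawn(1)[0], jitter=config.jitter_baselines
    )
    rho_windows: list[dict[str, np.ndarray]] = []
    for p, s in enumerate(seed_pairs.spawn(config.n_pairs)):
        win = pair_correlation_traces(
            pair_models[2 * p], pair_models[2 * p + 1], waves, config.n_trials, s, config
        )
        rho_windows.append(win)
        for subset, value in _unit_scores(win, stim, signs, config, "correlation").items():
            inv_rows.append(
                {
                    "unit_id": f"pair{p}",
                    "stage": "correlated_afferent",
                    "subset": subset,
                    "level": "correlation",
                    "invariance": value,
                }
            )

    # --- ELL pyramidal cells ------------------------------------------------
    logger.info("simulating %d ON and %d OFF pyramidal cells", config.n_ell_on, config.n_ell_off)
    ell_windows: dict[str, list[dict[str, np.ndarray]]] = {"ELL_ON": [], "ELL_OFF": []}
    ell_seeds = seed_ell.spawn(config.n_ell_on + config.n_ell_off)
    ell_models = syn.make_population(
        "ELL_ON", config.n_ell_on, seed_pop.spawn(2)[1], jitter=config.jitter_baselines
    ) + [
        dataclasses.replace(m, stage="ELL_OFF")
        for m in syn.make_population(
            "ELL_OFF", config.n_ell_off, seed_pop.spawn(3)[2], jitter=config.jitter_baselines
        )
    ]
    for u, (model, s) in enumerate(zip(ell_models, ell_seeds)):
        win, resp, _ = pyramidal_response_traces(model, waves, config.n_trials, s, config)
        ell_windows[model.stage].append(win)
        uid = f"{model.stage.lower()}{u}"
        for label, rv in resp.items():
            resp_rows.append(
                {
                    "unit_id": uid,
                    "stage": model.stage,
                    "waveform_label": label,
                    "phase_deg": phase_of[label],
                    "response": rv.value,
                }
            )
        for subset, value in _unit_scores(win, stim, signs, config, "single_unit").items():
            inv_rows.append(
                {
                    "unit_id": uid,
                    "stage": model.stage,
                    "subset": subset,
                    "level": "single_unit",
                    "invariance": value,
                }
            )

    # --- TS neurons ----------------------------------------------------------
    logger.info("simulating %d TS neurons", config.n_ts)
    ts_models = syn.make_population(
        "TS", config.n_ts, seed_pop.spawn(4)[3], jitter=config.jitter_baselines
    )
    ts_windows: list[dict[str, np.ndarray]] = []
    for u, (model, s) in enumerate(zip(ts_models, seed_ts.spawn(config.n_ts))):
        win, resp, _ = ts_response_traces(model, waves, config.n_trials, s, config)
        ts_windows.append(win)
        for label, rv in resp.items():
            resp_rows.append(
                {
                    "unit_id": f"ts{u}",
                    "stage": "TS",
                    "waveform_label": label,
                    "phase_deg": phase_of[label],
                    "response": rv.value,
                }
            )
        for subset, value in _unit_scores(win, stim, signs, config, "single_unit").items():
            inv_rows.append(
                {
                    "unit_id": f"ts{u}",
                    "stage": "TS",
                    "subset": subset,
                    "level": "single_unit",
                    "invariance": value,
                }
            )
    ts_pop_windows = {
        label: np.sum([win[label] for win in ts_windows], axis=0) for label in stim
    }
    for subset, value in _unit_scores(ts_pop_windows, stim, signs, config, "population").items():
        inv_rows.append(
            {
                "unit_id": "ts_population",
                "stage": "TS",
                "subset": subset,
                "level": "population",
                "invariance": value,
            }
        )

    # --- behavior -------------------------------------------------------------
    logger.info("simulating echo responses for %d fish", config.n_fish)
    bhv_windows, bhv_table = behavioral_experiment(config, seed_behavior)
    for subset, value in _unit_scores(bhv_windows, stim, signs, config, "behavior").items():
        inv_rows.append(
            {
                "unit_id": "behavior_pooled",
                "stage": "behavior",
                "subset": subset,
                "level": "behavior",
                "invariance": value,
            }
        )
    for _, row in bhv_table.iterrows():
        resp_rows.append(
            {
                "unit_id": row["fish_id"],
                "stage": "behavior",
                "waveform_label": row["waveform_label"],
                "phase_deg": row["phase_deg"],
                "response": row["behavior_response"],
            }
        )

    invariance = pd.DataFrame(inv_rows)
    responses = pd.DataFrame(resp_rows)

    # tuning curves per stage (population mean +/- SEM across units)
    tuning = {}
    for stage in ["afferent", "ELL_ON", "ELL_OFF", "TS"]:
        sub = responses[responses.stage == stage]
        per_unit = {
            unit: dict(zip(g["phase_deg"], g["response"]))
            for unit, g in sub.groupby("unit_id")
        }
        tuning[stage] = inv.build_tuning_curve(per_unit)

    result = PipelineResult(
        config=config,
        waves=waves,
        invariance=invariance,
        responses=responses,
        signs=signs,
        tuning=tuning,
        behavior_stats=bhv_table,
    )
    result.summary = summarize(result, boot_seed=seed_boot)
    if config.outdir:
        _write_outputs(result)
    return result


def summarize(result: PipelineResult, boot_seed=None) -> dict:
    """Per-stage invariance summary: mean +/- SEM, max, min, population value.

    Neural stages use the standard error across units; the behavioral SEM
    uses the moving-block bootstrap (block 27) over the per-presentation
    log rate ratios, matching how behavioral error bars are estimated.
    """
    if result.invariance.empty:
        raise ValueError("empty result bundle")
    df = result.invariance
    config = result.config
    summary: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "signs": result.signs,
        "stages": {},
    }
    stage_levels = [
        ("afferent", "single_unit"),
        ("correlated_afferent", "correlation"),
        ("ELL_ON", "single_unit"),
        ("ELL_OFF", "single_unit"),
        ("TS", "single_unit"),
        ("behavior", "behavior"),
    ]
    for stage, level in stage_levels:
        sub = df[(df.stage == stage) & (df.level == level) & (df.subset == "all")]
        if sub.empty:
            continue
        values = sub["invariance"].to_numpy()
        entry = {
            "mean": float(values.mean()),
            "max": float(values.max()),
            "min": float(values.min()),
            "n": int(values.size),
        }
        if values.size > 1:
            entry["sem"] = float(values.std(ddof=1) / np.sqrt(values.size))
        pop = df[(df.stage == stage) & (df.level == "population") & (df.subset == "all")]
        if not pop.empty:
            entry["population"] = float(pop["invariance"].iloc[0])
        summary["stages"][stage] = entry
    # subset table
    summary["subsets"] = {
        stage: {
            subset: float(
                df[(df.stage == stage) & (df.subset == subset) & (df.level != "population")][
                    "invariance"
                ].mean()
            )
            for subset in ["all", "++/--", "+-"]
        }
        for stage in df.stage.unique()
    }
    # TS high-invariance subgroup
    ts = df[(df.stage == "TS") & (df.level == "single_unit") & (df.subset == "all")]
    high = ts[ts.invariance > config.ts_high_invariance_threshold]
    summary["ts_high_invariance"] = {
        "threshold": config.ts_high_invariance_threshold,
        "n": int(high.shape[0]),
        "mean": float(high["invariance"].mean()) if not high.empty else None,
    }
    if result.behavior_stats is not None and not result.behavior_stats.empty:
        series = result.behavior_stats["behavior_response"].to_numpy()
        # pooled log rate ratio per the behavioral response definition:
        # rates pooled over presentations, floored at one event per pooled
        # window
        stats = result.behavior_stats
        n_pres = stats.shape[0]
        floor = 1.0 / n_pres
        cr_chirp = max(float(stats["cr_chirp"].mean()), floor)
        cr_beat = max(float(stats["cr_beat"].mean()), floor)
        summary["behavior"] = {
            "pooled_response": float(np.log(cr_chirp / cr_beat)),
            "mean_response": float(series.mean()),
            "sem_block_bootstrap": bhv.block_bootstrap_sem(
                series, block=27, n_boot=config.n_boot, seed=boot_seed
            ),
            "mean_cr_chirp": float(result.behavior_stats["cr_chirp"].mean()),
            "mean_cr_beat": float(result.behavior_stats["cr_beat"].mean()),
        }
    return summary


def _write_outputs(result: PipelineResult) -> None:
    outdir = Path(result.config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": result.config.seed, "config_hash": result.config.config_hash()}
    result.invariance.to_csv(outdir / "invariance.tsv", sep="\t", index=False)
    result.responses.to_csv(outdir / "responses.tsv", sep="\t", index=False)
    if result.behavior_stats is not None:
        result.behavior_stats.to_csv(outdir / "behavior.tsv", sep="\t", index=False)
    (outdir / "summary.json").write_text(json.dumps(result.summary, indent=2))
    (outdir / "config.json").write_text(
        json.dumps({**result.config.to_dict(), **meta}, indent=2)
    )
    logger.info("wrote outputs to %s", outdir)
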