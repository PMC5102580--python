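"""End-to-end pipeline: simulate -> preprocess -> events -> screen ->
deconvolve -> components -> inference -> report.

The pipeline runs one or more simulated patients through the full analysis
and collects per-electrode deconvolved traces, dip/overshoot component
estimates (plugin and split-half), permutation-test results with FDR across
all visually responsive electrodes, and per-ROI randomization tests of
effect inhomogeneity. One global seed deterministically derives every
per-stage, per-patient seed; re-running an identical configuration
reproduces every stochastic output bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import deconvolution as dc
from . import inference as inf
from . import responsiveness as rsp
from . import signal_hfb as sh
from . import synthetic as syn
from .components import (ComponentEstimate, quantify_components,
                         split_half_component)
from .events import write_events
from .ocular import detect_blinks_pupil

STAGES = ["simulate", "preprocess", "ocular", "screen", "deconvolve",
          "components", "inference", "report"]


class InputMissingError(FileNotFoundError):
    pass


@dataclass(frozen=True)
class PatientSpec:
    name: str
    rois: tuple


@dataclass(frozen=True)
class PipelineConfig:
    simulation: syn.SimulationConfig = syn.SimulationConfig()
    patients: tuple = (
        PatientSpec("P01", ("V1", "V1", "V2", "V3", "FC", "FC", "N-FC", "N-FC")),
        PatientSpec("P02", ("V1", "V2", "V4", "VO", "FC", "N-FC", "N-FC")),
    )
    fidelity: str = "hfb"             # 'hfb' | 'raw'
    simulate_ocular: bool = True
    input_path: str | None = None     # load instead of simulate (unset: simulate)
    stim_window_ms: tuple = (0.0, 1500.0)
    inter_window_ms: tuple = (-250.0, 500.0)
    interruption_types: tuple = ("gap", "spontaneous", "voluntary")
    contrasts: tuple = (("gap", "spontaneous"), ("gap", "voluntary"))
    m_permutations: int = 2000
    n_splits: int = 30
    m_randomization: int = 10000
    alpha: float = 0.05
    glass_min: float = 2.0
    truth_params: tuple = ()          # extra kwargs for GroundTruth.from_rois
    output_dir: str | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=lambda o: list(o)))

    def config_hash(self) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim = syn.SimulationConfig(**d.pop("simulation", {}))
        pats = tuple(PatientSpec(p["name"], tuple(p["rois"]))
                     for p in d.pop("patients", []))
        kw = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        if pats:
            kw["patients"] = pats
        return cls(simulation=sim, **kw)


def excluded_timepoints(events: pd.DataFrame, n: int, rate: float,
                        rejection_mask: np.ndarray | None = None,
                        extra_intervals=()) -> np.ndarray:
    """Timepoints removed from deconvolution: whole animal trials, whole
    trials touched by the artifact mask or by ambiguous ocular intervals."""
    mask = np.zeros(n, dtype=bool)
    if rejection_mask is not None:
        mask |= rejection_mask
    for a, b in extra_intervals:
        mask[max(0, int(a * rate)):min(n, int(np.ceil(b * rate)))] = True
    stim = events[events["kind"] == "stimulus"]
    spans = np.round(stim[["onset_s", "offset_s"]].to_numpy() * rate).astype(int)
    for (i0, i1), cat in zip(spans, stim["category"]):
        i0, i1 = max(0, i0), min(n, i1)
        if cat == "animal" or mask[i0:i1].any():
            mask[i0:i1] = True
    return mask


def _present_types(events: pd.DataFrame, wanted, min_events: int = 4) -> list:
    """Interruption types with enough usable (face / non-face trial) events
    to support deconvolution; sparser types are skipped."""
    have = []
    for t in wanted:
        if len(_interruption_events(events, t)) >= min_events:
            have.append(t)
    return have


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report bundle (and writes outputs
    plus a manifest when ``output_dir`` is set)."""
    t_start = time.time()
    if config.input_path is not None and not Path(config.input_path).exists():
        raise InputMissingError(
            f"input path {config.input_path!r} does not exist and simulation "
            "is disabled")
    root = np.random.SeedSequence(config.seed)
    patient_seeds = root.spawn(len(config.patients))
    bundle = {"config": config, "patients": {}, "stage_log": []}
    log = bundle["stage_log"]

    all_results = []         # responsiveness, pooled
    all_perm = {}            # (contrast, component) -> list of PermutationResult
    all_components = []

    for pat, pseed in zip(config.patients, patient_seeds):
        s_sim, s_oc, s_split, s_perm = pseed.spawn(4)
        pdata = {"name": pat.name}
        bundle["patients"][pat.name] = pdata

        # --- simulate -----------------------------------------------------
        truth = syn.GroundTruth.from_rois(
            pat.rois, stim_window_ms=config.stim_window_ms,
            inter_window_ms=config.inter_window_ms,
            **dict(config.truth_params))
        sim = config.simulation
        rng_sim = np.random.default_rng(s_sim)
        if config.fidelity == "raw":
            # preprocess() runs the widespread-artifact scan on the envelope
            rec, schedule = syn.generate_raw_session(sim, truth, rng_sim)
            hfb = sh.preprocess(rec, syn.baseline_intervals_for(sim))
        else:
            # HFB-level sessions are artifact-free by construction; the
            # outlier scan would flag the synchronized stimulus transients
            # that every simulated channel shares
            hfb, schedule = syn.generate_hfb_session(sim, truth, rng_sim)
        pdata["truth"] = truth
        pdata["events"] = schedule
        pdata["hfb"] = hfb
        n = hfb.n_samples

        # --- ocular -------------------------------------------------------
        ambiguous = []
        if config.simulate_ocular:
            oc = syn.generate_ocular_channels(sim, schedule,
                                              np.random.default_rng(s_oc))
            det = detect_blinks_pupil(oc.pupil, oc.eog, oc.rate)
            pdata["ocular"] = {"n_true": len(oc.true_onsets_s),
                               "n_detected": len(det.blinks),
                               "ambiguous": det.ambiguous_intervals}
            ambiguous = det.ambiguous_intervals

        # --- screen -------------------------------------------------------
        results = rsp.score_visual_responsiveness(
            hfb, schedule, alpha=config.alpha, glass_min=config.glass_min)
        rsp.score_face_selectivity(hfb, schedule, results)
        metadata = pd.DataFrame({
            "electrode": [el.name for el in truth.electrodes],
            "roi": ["N-FC" if el.roi == "FC" else el.roi
                    for el in truth.electrodes],
        })
        rsp.assign_rois(metadata, results)
        for r in results:
            r.patient = pat.name
        pdata["screening"] = results
        all_results.extend(results)
        visual_idx = [i for i, r in enumerate(results) if r.selected]

        # --- deconvolve (reduced model, no category split) -----------------
        types = _present_types(schedule, config.interruption_types)
        excl = excluded_timepoints(schedule, n, hfb.rate,
                                   hfb.rejection_mask, ambiguous)
        pdata["excluded_fraction"] = float(excl.mean())
        traces = {}
        fits = {}
        for lock in ("onset", "offset"):
            spec = dc.DesignSpec(tuple(
                dc.stimulus_sets(False, config.stim_window_ms) +
                dc.interruption_sets(types, lock, False,
                                     config.inter_window_ms)), rate=hfb.rate)
            design = dc.build_design_matrix(schedule, spec, n, excl)
            for c in visual_idx:
                fit = dc.fit_ols(design, hfb.values[c], drop_collinear=True)
                dc.hc3_standard_errors(fit)
                fits[(c, lock)] = fit
                for t in types:
                    traces[(c, t, lock)] = fit.trace(t)
        pdata["traces"] = traces
        pdata["types"] = types

        # --- components ----------------------------------------------------
        comps = []
        rng_split = np.random.default_rng(s_split)
        for t in types:
            others = [u for u in types if u != t]
            for lock, comp, sign in (("onset", "dip", -1),
                                     ("offset", "overshoot", +1)):
                spec = dc.DesignSpec(tuple(
                    dc.stimulus_sets(False, config.stim_window_ms) +
                    dc.interruption_sets(others, lock, False,
                                         config.inter_window_ms)),
                    rate=hfb.rate)
                fixed = dc.build_design_matrix(schedule, spec, n, excl)
                ev = _interruption_events(schedule, t)
                times = (ev["onset_s"] if lock == "onset"
                         else ev["offset_s"]).to_numpy()
                strata = ev["category"].to_numpy()
                refit = dc.RelabelRefitter(fixed, times,
                                           config.inter_window_ms)
                for c in visual_idx:
                    name = hfb.channel_names[c]
                    plug_on = traces[(c, t, "onset")]
                    plug_off = traces[(c, t, "offset")]
                    dip, over = quantify_components(
                        (plug_on[0], plug_on[1]), (plug_off[0], plug_off[1]),
                        electrode=name, interruption=t)
                    plug = dip if comp == "dip" else over
                    refit.set_y(hfb.values[c])
                    sh_val = split_half_component(
                        refit, sign, n_splits=config.n_splits,
                        rng=np.random.default_rng(rng_split.integers(2**31)),
                        strata=(strata == "face").astype(int))
                    comps.append({"patient": pat.name, "electrode": name,
                                  "roi": results[c].roi,
                                  "interruption": t, "component": comp,
                                  "plugin": plug.integral,
                                  "split_half": sh_val,
                                  "interval_ms": plug.interval_ms})
        pdata["components"] = comps
        all_components.extend(comps)

        # --- inference (permutations per electrode) -------------------------
        rng_perm = np.random.default_rng(s_perm)
        for gap_t, blink_t in config.contrasts:
            if gap_t not in types or blink_t not in types:
                continue
            gap_ev = _interruption_events(schedule, gap_t)
            blink_ev = _interruption_events(schedule, blink_t)
            pooled = pd.concat([gap_ev, blink_ev])
            is_gap = np.concatenate([np.ones(len(gap_ev), bool),
                                     np.zeros(len(blink_ev), bool)])
            strata = (pooled["category"] == "face").to_numpy().astype(int)
            others = [u for u in types if u not in (gap_t, blink_t)]
            for lock, comp in (("onset", "dip"), ("offset", "overshoot")):
                spec = dc.DesignSpec(tuple(
                    dc.stimulus_sets(False, config.stim_window_ms) +
                    dc.interruption_sets(others, lock, False,
                                         config.inter_window_ms)),
                    rate=hfb.rate)
                fixed = dc.build_design_matrix(schedule, spec, n, excl)
                times = (pooled["onset_s"] if lock == "onset"
                         else pooled["offset_s"]).to_numpy()
                refit = dc.RelabelRefitter(fixed, times,
                                           config.inter_window_ms)
                key = (f"{gap_t}_vs_{blink_t}", comp)
                for c in visual_idx:
                    refit.set_y(hfb.values[c])
                    res = inf.permutation_component_test(
                        refit, is_gap, comp, m=config.m_permutations,
                        rng=np.random.default_rng(rng_perm.integers(2**31)),
                        strata=strata, electrode=hfb.channel_names[c],
                        contrast=key[0], degenerate="fix")
                    res.patient = pat.name
                    res.roi = results[c].roi
                    all_perm.setdefault(key, []).append(res)
        log.append({"stage": "patient", "name": pat.name,
                    "n_events": len(schedule),
                    "n_visual": len(visual_idx),
                    "excluded_fraction": pdata["excluded_fraction"]})

    # --- FDR across all visually responsive electrodes, ROI tests ----------
    inference_tables = {}
    roi_tests = {}
    rng_rand = np.random.default_rng(root.spawn(1)[0])
    for key, res_list in all_perm.items():
        df = inf.fdr_across_electrodes(res_list)
        inference_tables[key] = df
        assigned = df[df["roi"].notna() & (df["roi"] != "unassigned")]
        if len(assigned):
            counts = assigned.groupby("roi").agg(
                n=("electrode", "size"),
                O=("p_fdr", lambda p: int(((p < config.alpha) &
                   (assigned.loc[p.index, "observed"] > 0)).sum())))
            roi_tests[key] = inf.randomization_independence_test(
                counts["O"].to_numpy(), counts["n"].to_numpy(),
                m=config.m_randomization, seed=rng_rand)
            roi_tests[key].counts_table = counts

    bundle["inference"] = inference_tables
    bundle["roi_tests"] = roi_tests
    bundle["components_table"] = pd.DataFrame(all_components)
    bundle["screening_table"] = rsp.results_table(all_results)
    bundle["report"] = make_report(bundle)
    bundle["manifest"] = {
        "stages": STAGES,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_patients": len(config.patients),
        "elapsed_s": round(time.time() - t_start, 2),
        "log": log,
    }
    if config.output_dir:
        _write_outputs(bundle, Path(config.output_dir))
    return bundle


def _interruption_events(events: pd.DataFrame, etype: str) -> pd.DataFrame:
    if etype == "gap":
        ev = events[events["kind"] == "gap"]
    else:
        ev = events[(events["kind"] == "blink") &
                    (events["subtype"] == etype)]
    return ev[ev["category"].isin(["face", "nonface"])]


def make_report(bundle: dict) -> dict:
    """Summary tables: per-ROI grand-average traces (averaged within, then
    across patients), component means per ROI x interruption, and
    significant-electrode counts per ROI."""
    patients = bundle["patients"]
    grand = {}
    per_patient = {}
    for name, pdata in patients.items():
        traces = pdata.get("traces", {})
        screening = pdata.get("screening", [])
        for (c, t, lock), (lags, beta, _) in traces.items():
            roi = screening[c].roi if c < len(screening) else None
            if roi in (None, "unassigned"):
                continue
            per_patient.setdefault((roi, t, lock), {}) \
                .setdefault(name, []).append((lags, beta))
    for key, by_pat in per_patient.items():
        pat_means = []
        lags = None
        for name, tr_list in by_pat.items():
            lags = tr_list[0][0]
            pat_means.append(np.mean([b for _, b in tr_list], axis=0))
        grand[key] = (lags, np.mean(pat_means, axis=0), len(pat_means))

    comp = bundle.get("components_table", pd.DataFrame())
    comp_summary = (comp.groupby(["roi", "interruption", "component"])
                    [["plugin", "split_half"]].mean().reset_index()
                    if len(comp) else pd.DataFrame())
    sig = {}
    for key, df in bundle.get("inference", {}).items():
        alpha = bundle["config"].alpha
        d = df[df["roi"].notna() & (df["roi"] != "unassigned")]
        sig[key] = (d.assign(significant=(d["p_fdr"] < alpha) &
                             (d["observed"] > 0))
                    .groupby("roi")["significant"].agg(["sum", "size"]))
    return {"grand_average": grand, "component_summary": comp_summary,
            "significance_by_roi": sig}


def _write_outputs(bundle: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for name, pdata in bundle["patients"].items():
        write_events(pdata["events"], out / f"{name}_events.tsv")
    bundle["screening_table"].to_csv(out / "screening.tsv", sep="\t",
                                     index=False)
    export_components(bundle["components_table"], out / "components.tsv")
    for (contrast, comp), df in bundle["inference"].items():
        df.to_csv(out / f"inference_{contrast}_{comp}.tsv", sep="\t",
                  index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=1)


def export_components(table: pd.DataFrame, path, *,
                      log_transform: bool = False) -> pd.DataFrame:
    """Long-format component table for external (mixed-effects) fitting.

    With ``log_transform``, dip magnitudes are sign-inverted, all values are
    uniformly shifted above zero, and logged — the variance-stabilizing
    transform used before mixed-model fitting.
    """
    t = table.copy()
    if log_transform and len(t):
        v = t["split_half"].to_numpy().copy()
        v[t["component"] == "dip"] *= -1.0
        shift = max(0.0, 1e-3 - v.min())
        t["log_value"] = np.log(v + shift)
        t.attrs["shift"] = shift
    if path is not None:
        t.to_csv(path, sep="\t", index=False)
    return t
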