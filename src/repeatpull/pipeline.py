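"""End-to-end orchestration: simulate -> analyze -> report.

:func:`run_pipeline` takes a JSON-style config describing synthetic
cohorts (typically 12 bound + 12 free runs, mirroring the study design)
or existing force-trace files, runs every analysis stage — force-peak
identification, WLC contour lengths and periodicity, work transfer and
per-repeat comparisons, unfolding order with the exact Fisher test,
contact and binding lifetimes — and writes a deterministic report bundle
(TSV/JSON) plus a manifest with config snapshot, seeds and output
checksums.  Re-running with the same config and seed reproduces the
bundle byte for byte.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import contact_analysis as ca
from . import force_peaks as fp
from . import unfolding_order as uo
from . import wlc_fit as wf
from . import work_transfer as wt
from .constants import kbt
from .errors import ConfigError, RepeatPullError
from .synthetic_pulling import (SimParams, make_native_template,
                                simulate_pull, synthesize_trajectory)
from .trajio import (read_force_trace, write_contingency_table,
                     write_force_trace, write_json, write_table)

__all__ = ["run_pipeline", "default_config"]

_SIM_KEYS = set(SimParams.__dataclass_fields__)


def default_config() -> dict:
    """Study-design defaults: 12 free + 12 bound runs at 0.01 Å/ps."""
    return {
        "seed": 0,
        "sim": {"speed": 0.01, "spring_k": 20.0, "n_repeats": 7},
        "cohorts": {
            "free": {"n_runs": 12, "ligand": False, "q_whole": 0.3},
            "bound": {"n_runs": 12, "ligand": True, "ddg": 4.0,
                      "q_whole": 0.9},
        },
        "peaks": {"bin_width": 5.0, "min_prominence": 30.0,
                  "smooth_window": 5, "threshold": "auto",
                  "fallback_threshold": 100.0},
        "wlc": {"persistence": 3.8, "bin_width": 5.0},
        "unfold": {"rmsd_threshold": 10.0, "kde_bandwidth_ps": 1600.0},
        "contacts": {"cutoff": 8.0, "min_seq_sep": 3, "min_run_ps": 400.0,
                     "binding_cutoff": 5.0, "native_fraction": 0.8},
        "synthesize": True,
        "trajectory": {"frame_interval": 40.0, "window": 1600.0,
                       "jitter": 0.3},
        "template": {"residues_per_repeat": 12},
        "write_traces": False,
    }


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def _validate(config: dict) -> None:
    if "cohorts" not in config or not config["cohorts"]:
        raise ConfigError("config must name at least one cohort")
    for name, cohort in config["cohorts"].items():
        if "traces" in cohort:
            continue
        if "n_runs" not in cohort:
            raise ConfigError(f"cohort {name}: need n_runs or traces")
        unknown = set(cohort) - _SIM_KEYS - {"n_runs"}
        if unknown:
            raise ConfigError(f"cohort {name}: unknown keys {sorted(unknown)}")
    unknown = set(config.get("sim", {})) - _SIM_KEYS
    if unknown:
        raise ConfigError(f"sim: unknown keys {sorted(unknown)}")


def _child_seed(base: int, *path: int) -> int:
    ss = np.random.SeedSequence([int(base), *[int(p) for p in path]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _stage(name: str, run_id=None):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, RepeatPullError):
                raise RepeatPullError(
                    f"stage {name}"
                    + (f" run {run_id}" if run_id is not None else "")
                    + f": {exc}") from exc
            return False
    return _Ctx()


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Run the full analysis pipeline and write the report bundle.

    Returns the summary dictionary that is also written to
    ``summary.json``.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = json.load(fh)
    if "cohorts" not in config:
        raise ConfigError("config must name cohorts (synthetic parameters "
                          "or input traces)")
    defaults = default_config()
    del defaults["cohorts"]           # cohorts are never defaulted
    config = _merge(defaults, config)
    _validate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    summary: dict = {"cohorts": {}}
    written: list[Path] = []

    cohort_names = sorted(config["cohorts"])
    traces_by_cohort: dict[str, list] = {}
    truths_by_cohort: dict[str, list] = {}

    # ---- simulate or load -------------------------------------------------
    for ci, name in enumerate(cohort_names):
        cohort = config["cohorts"][name]
        traces, truths = [], []
        if "traces" in cohort:
            with _stage("load", name):
                for path in cohort["traces"]:
                    traces.append(read_force_trace(path))
                    truths.append(None)
        else:
            sim_kwargs = {k: v for k, v in config.get("sim", {}).items()}
            sim_kwargs.update({k: v for k, v in cohort.items()
                               if k in _SIM_KEYS})
            params = SimParams(**sim_kwargs)
            for ri in range(int(cohort["n_runs"])):
                with _stage("simulate", f"{name}/{ri}"):
                    trace, truth = simulate_pull(
                        params, _child_seed(seed, ci, ri))
                traces.append(trace)
                truths.append(truth)
                if config.get("write_traces"):
                    path = out / f"trace_{name}_{ri:02d}.tsv"
                    write_force_trace(trace, path)
                    written.append(path)
        traces_by_cohort[name] = traces
        truths_by_cohort[name] = truths

    # ---- peaks, WLC, periodicity ------------------------------------------
    pk_cfg, wlc_cfg = config["peaks"], config["wlc"]
    fits_by_cohort: dict[str, dict] = {}
    for name in cohort_names:
        traces = traces_by_cohort[name]
        with _stage("threshold", name):
            pooled = np.concatenate([t.force_magnitude for t in traces])
            if pk_cfg["threshold"] == "auto":
                fit = fp.fit_force_distribution(pooled, pk_cfg["bin_width"])
                try:
                    threshold, reliable = fp.select_threshold(fit)
                except fp.ThresholdError:
                    threshold, reliable = pk_cfg["fallback_threshold"], False
                if not reliable:
                    threshold = pk_cfg["fallback_threshold"]
            else:
                threshold, reliable = float(pk_cfg["threshold"]), True
        rows, fits_by_run = [], {}
        for ri, trace in enumerate(traces):
            with _stage("peaks", f"{name}/{ri}"):
                peaks = fp.detect_peaks(
                    trace, threshold, pk_cfg["min_prominence"],
                    pk_cfg["smooth_window"], run_id=ri)
                fits = wf.fit_trace_peaks(trace, peaks,
                                          wlc_cfg["persistence"])
            fits_by_run[ri] = fits
            for p in peaks:
                rows.append({"run": ri, "time_ps": p.time,
                             "extension_A": p.extension,
                             "force_pN": p.force,
                             "prominence_pN": p.prominence})
        fits_by_cohort[name] = fits_by_run
        path = out / f"peaks_{name}.tsv"
        write_table(pd.DataFrame(
            rows, columns=["run", "time_ps", "extension_A", "force_pN",
                           "prominence_pN"]), path)
        written.append(path)

        with _stage("periodicity", name):
            hist = wf.contour_length_differences(fits_by_run,
                                                 wlc_cfg["bin_width"])
            period = score = None
            if hist.differences.size >= 10:
                period, score = wf.estimate_periodicity(hist)
        fit_rows = [{"run": ri, "peak": f.peak_id,
                     "contour_length_A": f.contour_length,
                     "residual_rms_pN": f.residual_rms}
                    for ri, fits in fits_by_run.items() for f in fits]
        path = out / f"wlc_fits_{name}.tsv"
        write_table(pd.DataFrame(
            fit_rows, columns=["run", "peak", "contour_length_A",
                               "residual_rms_pN"]), path)
        written.append(path)
        path = out / f"contour_diff_hist_{name}.tsv"
        write_table(pd.DataFrame({"bin_center_A": hist.bin_centers,
                                  "count": hist.counts}), path)
        written.append(path)
        summary["cohorts"][name] = {
            "threshold_pN": float(threshold),
            "n_peaks": int(sum(len(v) for v in fits_by_run.values())),
            "period_A": period, "period_score": score,
        }

    # ---- work transfer -----------------------------------------------------
    kb = kbt()
    works_by_cohort: dict[str, np.ndarray] = {}
    comps_by_cohort: dict[str, np.ndarray] = {}
    for name in cohort_names:
        traces = traces_by_cohort[name]
        totals, comps = [], []
        for ri, trace in enumerate(traces):
            with _stage("work", f"{name}/{ri}"):
                profile = (wt.repeat_work_components(trace, run_id=ri)
                           if trace.anchors is not None
                           else wt.cumulative_work(trace, run_id=ri))
            totals.append(profile.final_total / kb)
            if profile.components is not None:
                comps.append(profile.components[-1] / kb)
        works_by_cohort[name] = np.asarray(totals)
        comps_by_cohort[name] = (np.asarray(comps) if comps
                                 else np.empty((0, 0)))
        df = pd.DataFrame({"run": np.arange(len(totals)),
                           "total_work_kbt": totals})
        for r in range(comps_by_cohort[name].shape[1]):
            df[f"W_r{r + 1}_kbt"] = comps_by_cohort[name][:, r]
        path = out / f"work_{name}.tsv"
        write_table(df, path)
        written.append(path)
        summary["cohorts"][name]["mean_total_work_kbt"] = float(
            np.mean(totals))

    if len(cohort_names) == 2 and all(
            w.size >= 3 for w in works_by_cohort.values()):
        a, b = cohort_names
        with _stage("work-comparison"):
            t, p, sig = wt.compare_work(works_by_cohort[a],
                                        works_by_cohort[b])
            comparison = {"groups": [a, b], "total":
                          {"t": t, "p": p, "significant_1pct": sig}}
            ca_, cb_ = comps_by_cohort[a], comps_by_cohort[b]
            if ca_.size and cb_.size and ca_.shape[1] == cb_.shape[1]:
                per_rep = {}
                for r in range(ca_.shape[1]):
                    t, p, sig = wt.compare_work(ca_[:, r], cb_[:, r])
                    per_rep[f"r{r + 1}"] = {"t": t, "p": p,
                                            "significant_1pct": sig}
                comparison["per_repeat"] = per_rep
        path = out / "work_comparison.json"
        write_json(comparison, path)
        written.append(path)
        summary["work_comparison"] = comparison

    # ---- unfolding order / contacts (synthetic cohorts only) ---------------
    if config.get("synthesize") and all(
            truths_by_cohort[n][0] is not None for n in cohort_names):
        tr_cfg = config["trajectory"]
        un_cfg = config["unfold"]
        ct_cfg = config["contacts"]
        events_by_cohort: dict[str, list] = {}
        for ci, name in enumerate(cohort_names):
            cohort_sim = config["cohorts"][name]
            n_reps = truths_by_cohort[name][0].params.n_repeats
            lig_reps = (tuple(range(1, n_reps)) if cohort_sim.get("ligand")
                        else ())
            template = make_native_template(
                n_reps, config["template"]["residues_per_repeat"],
                seed=0, ligand_repeats=lig_reps)
            run_events, midpoint_rows = [], []
            presence_runs, binding_records = [], []
            contacts = ca.native_contacts(template.coords, template.topology,
                                          template.repeat_map,
                                          ct_cfg["cutoff"],
                                          ct_cfg["min_seq_sep"])
            common_times = None
            for ri, truth in enumerate(truths_by_cohort[name]):
                with _stage("synthesize", f"{name}/{ri}"):
                    traj = synthesize_trajectory(
                        truth, template, _child_seed(seed, 100 + ci, ri),
                        frame_interval=tr_cfg["frame_interval"],
                        window=tr_cfg["window"], jitter=tr_cfg["jitter"])
                with _stage("unfold", f"{name}/{ri}"):
                    rmsd = uo.repeat_rmsd(traj, template.repeat_map,
                                          template.coords)
                    events, _ = uo.unfolding_midpoints(
                        rmsd, traj.times, un_cfg["rmsd_threshold"],
                        run_id=ri)
                run_events.append(events)
                midpoint_rows += [{"run": ri, "repeat": ev.repeat_id,
                                   "midpoint_ps": ev.time, "rank": ev.rank}
                                  for ev in events]
                with _stage("contacts", f"{name}/{ri}"):
                    presence_runs.append(
                        ca.contact_presence(traj, contacts,
                                            ct_cfg["cutoff"]))
                    if lig_reps:
                        first_mid = min(truth.repeat_midpoints.values())
                        equil_end = max(traj.times[0],
                                        0.5 * first_mid)
                        binding_records.append(ca.binding_analysis(
                            traj, (0.0, equil_end),
                            ct_cfg["binding_cutoff"],
                            ct_cfg["native_fraction"],
                            min_run=ct_cfg["min_run_ps"]))
                    common_times = traj.times if common_times is None \
                        else common_times[:min(len(common_times),
                                               len(traj.times))]
            events_by_cohort[name] = run_events

            path = out / f"unfolding_events_{name}.tsv"
            write_table(pd.DataFrame(
                midpoint_rows,
                columns=["run", "repeat", "midpoint_ps", "rank"]), path)
            written.append(path)

            table = uo.order_contingency(run_events, by="repeat")
            path = out / f"order_contingency_{name}.tsv"
            write_contingency_table(table.counts, table.row_labels, path)
            written.append(path)

            with _stage("contact-lifetimes", name):
                trimmed = [p[:len(common_times)] for p in presence_runs]
                cmap = ca.contact_lifetimes(trimmed, common_times, contacts,
                                            ct_cfg["min_run_ps"])
            path = out / f"contact_lifetimes_{name}.tsv"
            write_table(pd.DataFrame(
                {"res_i": [c.i for c in contacts],
                 "res_j": [c.j for c in contacts],
                 "class": [c.contact_class for c in contacts],
                 "mean_lifetime_ps": cmap.mean,
                 "sem_ps": cmap.sem}), path)
            written.append(path)

            if binding_records:
                residues, mean, sem = ca.binding_lifetime_map(binding_records)
                path = out / f"binding_lifetimes_{name}.tsv"
                write_table(pd.DataFrame(
                    {"residue": residues, "mean_lifetime_ps": mean,
                     "sem_ps": sem,
                     "native_binder": binding_records[0].native_binder}),
                    path)
                written.append(path)

        if len(cohort_names) == 2:
            a, b = cohort_names
            with _stage("fisher"):
                n_reps = max(ev.repeat_id for evs in events_by_cohort[a]
                             for ev in evs)
                fisher = {}
                for rid in range(1, n_reps + 1):
                    runs = events_by_cohort[a] + events_by_cohort[b]
                    conds = ([a] * len(events_by_cohort[a])
                             + [b] * len(events_by_cohort[b]))
                    tab = uo.order_contingency(
                        runs, by="condition", conditions=conds,
                        repeat_id=rid, n_positions=n_reps)
                    fisher[f"r{rid}"] = uo.fisher_exact_rxc(
                        tab, seed=_child_seed(seed, 999, rid))
            path = out / "fisher.json"
            write_json(fisher, path)
            written.append(path)
            summary["fisher_p"] = fisher

    # ---- summary + manifest -------------------------------------------------
    summary_path = out / "summary.json"
    write_json(summary, summary_path)
    written.append(summary_path)

    checksums = {}
    for path in sorted(written):
        checksums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {"config": {k: v for k, v in config.items()},
                "seed": seed, "outputs": checksums}
    write_json(manifest, out / "manifest.json")
    return summary
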