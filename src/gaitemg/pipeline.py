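"""End-to-end study orchestration: simulate/load -> segment -> kinematics
-> sEMG -> discrete and field statistics -> report artifacts.

`run_study` consumes one or more subjects, each contributing a baseline
trial and an induced-lameness trial, and produces the report bundle:

* ``asymmetry.csv``        per-stride asymmetry indices per condition
* ``emg_discrete.csv``     per-stride ARV (raw, % RVC, outlier flag) and
  activation onset/offset/duration per burst
* ``emg_norm_strides.csv`` 101-node amplitude-normalized envelope strides
* ``table1_like.csv``      mixed-model condition contrasts with FDR p-values
* ``spm_results.csv``      paired SPM clusters per continuous variable
* ``runlog.json``          strides used/excluded, thresholds, seed, verdicts
* ``plots/``               median +/- SD stride bands with significant
  clusters shaded

With several subjects the SPM pairs subject-level median strides; a
single-subject run pairs strides by index instead (the within-horse
comparison used when group-level variation swamps individual effects).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .discrete import (contrast_conditions, induction_sufficiency,
                       mirror_for_side)
from .errors import GaitEMGError
from .io_model import MUSCLES, Trial, interpolate_gaps, load_trial
from .kinematics import (GaitEvents, N_NODES, asymmetry_indices,
                         detect_hindlimb_impacts, joint_and_limb_angles,
                         time_normalize)
from .semg import (arv_rvc, detect_activation, envelope_rvc,
                   flag_arv_outliers, preprocess_emg, rvc_normalize,
                   segmentation_limb, stride_arv)
from .spm import SubjectStrideField, paired_spm
from .synthetic import scenario_preset, simulate_static, simulate_trial

_ASYM_VARS = ("min_diff_poll", "max_diff_poll", "min_diff_withers",
              "max_diff_withers", "min_diff_pelvis", "max_diff_pelvis",
              "hip_hike")


@dataclass
class RunConfig:
    """Analysis constants and inputs for one study run."""

    baseline_bundles: list = field(default_factory=list)
    induced_bundles: list = field(default_factory=list)
    scenario_baseline: str = ""   # preset name; used when no bundles given
    scenario_induced: str = ""
    n_subjects: int = 1
    amp_fraction: float = 0.10
    timing_fraction: float = 0.05
    outlier_sd: float = 2.0
    alpha: float = 0.05
    bonferroni_m: int = 0   # 0 = number of variables in the tested panel
    poll_threshold_mm: float = 13.0
    pelvis_threshold_mm: float = 5.0
    speed_correction: bool = False
    seed: int = 0
    out_dir: str = "gaitemg_run"
    make_plots: bool = True

    def validate(self):
        from .errors import ConfigurationError
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must be in (0, 1)")
        for v in (self.amp_fraction, self.timing_fraction, self.outlier_sd,
                  self.poll_threshold_mm, self.pelvis_threshold_mm):
            if v <= 0:
                raise ConfigurationError("thresholds must be positive")


@dataclass
class ProcessedTrial:
    trial: Trial
    events: GaitEvents
    asymmetry: pd.DataFrame
    emg: dict           # channel name -> ProcessedEMG
    arv: pd.DataFrame   # stacked stride_arv records
    condition_role: str  # 'baseline' or 'induced'


def _prepare(trial: Trial, role: str) -> ProcessedTrial:
    markers = {n: interpolate_gaps(m) for n, m in trial.markers.items()}
    trial = Trial(trial.meta, markers, trial.emg)
    events = detect_hindlimb_impacts(trial)
    asym = asymmetry_indices(trial, events)
    proc = {name: preprocess_emg(ch, trial.meta.fs_emg)
            for name, ch in trial.emg.items()}
    frames = []
    for name, p in proc.items():
        windows = events.stride_windows(segmentation_limb(p.side))
        frames.append(stride_arv(p, windows, trial.meta.subject_id, role))
    arv = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return ProcessedTrial(trial, events, asym, proc, arv, role)


def _subject_pairs(config: RunConfig):
    """Yield (subject_id, baseline Trial, induced Trial) per subject."""
    if config.baseline_bundles:
        if len(config.baseline_bundles) != len(config.induced_bundles):
            raise GaitEMGError("need matching baseline/induced bundle lists")
        for b, i in zip(config.baseline_bundles, config.induced_bundles):
            tb, ti = load_trial(b), load_trial(i)
            yield tb.meta.subject_id, tb, ti
    else:
        for k in range(config.n_subjects):
            sb = scenario_preset(config.scenario_baseline or "baseline")
            si = scenario_preset(config.scenario_induced or "iFL_moderate")
            sb = dataclasses.replace(sb, seed=config.seed + 1000 * k,
                                     subject_id=f"horse{k + 1}")
            si = dataclasses.replace(si, seed=config.seed + 1000 * k + 500,
                                     subject_id=f"horse{k + 1}")
            yield sb.subject_id, simulate_trial(sb)[0], simulate_trial(si)[0]


def _stride_fields(pt: ProcessedTrial, env_rvc: dict):
    """Time-normalized 101-node curves per continuous variable and stride."""
    out = {}
    t_emg = pt.trial.t_emg
    for name, p in pt.emg.items():
        key = (p.muscle, p.side)
        if key not in env_rvc or env_rvc[key] <= 0:
            continue
        sig = 100.0 * p.envelope25 / env_rvc[key]
        windows = pt.events.stride_windows(segmentation_limb(p.side))
        curves = [time_normalize(t_emg, sig, w, pt.trial.meta.trial_id, k, name)
                  for k, w in enumerate(windows)]
        out[f"emg_{name}"] = [c.values for c in curves if c.valid]
    angset = joint_and_limb_angles(pt.trial, pt.trial)
    t_kin = pt.trial.t_kin
    for vname, series in angset.angles.items():
        side = "left" if vname.endswith("_L") else "right"
        windows = pt.events.stride_windows(segmentation_limb(side))
        curves = [time_normalize(t_kin, series, w, pt.trial.meta.trial_id, k, vname)
                  for k, w in enumerate(windows)]
        out[f"angle_{vname}"] = [c.values for c in curves
                                 if c.valid and not np.isnan(c.values).any()]
    return out


def run_study(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Returns a summary dict (also serialized as ``runlog.json``) with the
    sufficiency verdicts, stride counts, and paths of the artifacts.
    Induction insufficiency is reported, not fatal; any stage error aborts
    with the stage named.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    try:
        subjects = list(_subject_pairs(config))
        stage = "preprocess"
        processed = [(sid, _prepare(tb, "baseline"), _prepare(ti, "induced"))
                     for sid, tb, ti in subjects]

        stage = "emg_discrete"
        arv_all = pd.concat([pt.arv for _, pb, pi in processed for pt in (pb, pi)],
                            ignore_index=True)
        arv_all = flag_arv_outliers(arv_all)
        base_recs = arv_all[arv_all["condition"] == "baseline"]
        rvc = arv_rvc(base_recs)
        env_rvc = envelope_rvc(base_recs)
        arv_all = rvc_normalize(arv_all, rvc)

        activation_frames = []
        for sid, pb, pi in processed:
            base_dur = float(np.mean([t1 - t0 for t0, t1
                                      in pb.events.stride_windows("HL")]))
            for pt in (pb, pi):
                for name, p in pt.emg.items():
                    windows = pt.events.stride_windows(segmentation_limb(p.side))
                    ev = detect_activation(p.envelope10, p.fs, windows, base_dur,
                                           config.amp_fraction,
                                           config.timing_fraction)
                    df = ev.records.copy()
                    df["subject"], df["condition"] = sid, pt.condition_role
                    df["muscle"], df["side"] = p.muscle, p.side
                    activation_frames.append(df)
        activation = pd.concat(activation_frames, ignore_index=True)
        emg_discrete = arv_all.merge(
            activation, on=["subject", "condition", "muscle", "side", "stride_index"],
            how="left")
        emg_discrete.to_csv(out / "emg_discrete.csv", index=False)

        stage = "asymmetry"
        asym_frames = []
        for sid, pb, pi in processed:
            for pt in (pb, pi):
                df = pt.asymmetry.copy()
                df["subject"], df["condition"] = sid, pt.condition_role
                side = pt.trial.meta.induction_side
                if side == "right":
                    df = mirror_for_side(df, side)
                asym_frames.append(df)
        asym_all = pd.concat(asym_frames, ignore_index=True)
        asym_all.to_csv(out / "asymmetry.csv", index=False)

        stage = "sufficiency"
        verdicts = {}
        for sid, pb, pi in processed:
            b = asym_all[(asym_all.subject == sid) & (asym_all.condition == "baseline")]
            i = asym_all[(asym_all.subject == sid) & (asym_all.condition == "induced")]
            verdicts[sid] = induction_sufficiency(b, i)

        stage = "mixed_models"
        rows = []
        for _, rec in asym_all.iterrows():
            for var in _ASYM_VARS + ("stride_duration",):
                if var in rec and np.isfinite(rec[var]):
                    rows.append({"subject": rec["subject"], "condition": rec["condition"],
                                 "variable": var, "value": rec[var],
                                 "stride_speed": rec["stride_speed"]})
        induction_side = processed[0][2].trial.meta.induction_side or "left"
        role_map = ({"left": "LS", "right": "NLS"} if induction_side != "right"
                    else {"left": "NLS", "right": "LS"})
        for _, rec in emg_discrete[~emg_discrete["outlier"]].iterrows():
            role = role_map[rec["side"]]
            rows.append({"subject": rec["subject"], "condition": rec["condition"],
                         "variable": f"arv_{rec['muscle']}_{role}",
                         "value": rec["arv_norm_pct"], "stride_speed": np.nan})
        table = pd.DataFrame(rows)
        contrasts = contrast_conditions(table, config.speed_correction)
        t1 = pd.DataFrame([dataclasses.asdict(c) for c in contrasts])
        t1.to_csv(out / "table1_like.csv", index=False)

        stage = "spm"
        spm_rows, spm_bands = [], {}
        fields = {"baseline": {}, "induced": {}}
        for sid, pb, pi in processed:
            for pt, role in ((pb, "baseline"), (pi, "induced")):
                for var, curves in _stride_fields(pt, env_rvc).items():
                    fields[role].setdefault(var, {})[sid] = curves
        panel = sorted(set(fields["baseline"]) & set(fields["induced"]))
        m_bonf = config.bonferroni_m or max(len(panel), 1)
        for var in panel:
            A, B = _paired_fields(fields, var, len(processed))
            if A is None:
                continue
            res = paired_spm(A, B, config.alpha, m_bonf)
            spm_bands[var] = (fields["baseline"][var], fields["induced"][var], res)
            if res.clusters:
                for c in res.clusters:
                    spm_rows.append({"variable": var, "df": res.df,
                                     "fwhm": res.fwhm,
                                     "threshold": res.critical_threshold,
                                     "cluster_start_pct": c["start_pct"],
                                     "cluster_end_pct": c["end_pct"],
                                     "p_value": c["p"]})
            else:
                spm_rows.append({"variable": var, "df": res.df, "fwhm": res.fwhm,
                                 "threshold": res.critical_threshold,
                                 "cluster_start_pct": np.nan,
                                 "cluster_end_pct": np.nan, "p_value": np.nan})
        spm_df = pd.DataFrame(spm_rows)
        spm_df.to_csv(out / "spm_results.csv", index=False)

        stage = "norm_strides"
        _write_norm_strides(out, fields)

        if config.make_plots:
            stage = "plots"
            _plot_bands(out / "plots", spm_bands)

        stage = "runlog"
        log = {
            "version": __version__,
            "seed": config.seed,
            "alpha": config.alpha,
            "amp_fraction": config.amp_fraction,
            "timing_fraction": config.timing_fraction,
            "outlier_sd": config.outlier_sd,
            "bonferroni_m": config.bonferroni_m,
            "sufficiency_thresholds_mm": {"poll": config.poll_threshold_mm,
                                          "pelvis": config.pelvis_threshold_mm},
            "subjects": [sid for sid, _, _ in processed],
            "strides_analyzed": {
                "baseline": int((asym_all.condition == "baseline").sum()),
                "induced": int((asym_all.condition == "induced").sum()),
            },
            "strides_excluded": int(asym_all["excluded"].sum()),
            "arv_outlier_strides": int(arv_all["outlier"].sum()),
            "sufficiency": verdicts,
            "significant_spm_variables": sorted(
                spm_df.dropna(subset=["p_value"])["variable"].unique().tolist())
            if len(spm_df) else [],
        }
        (out / "runlog.json").write_text(json.dumps(log, indent=2, sort_keys=True))
        return log
    except GaitEMGError as exc:
        raise GaitEMGError(f"stage {stage!r} failed: {exc}") from exc


def _paired_fields(fields, var, n_subjects):
    """Subject-paired median-stride fields, or stride-paired for n=1."""
    base = fields["baseline"][var]
    ind = fields["induced"][var]
    common = sorted(set(base) & set(ind))
    if not common:
        return None, None
    if len(common) >= 3:
        A = [SubjectStrideField(s, "induced", var, np.median(ind[s], axis=0))
             for s in common if len(ind[s]) and len(base[s])]
        B = [SubjectStrideField(s, "baseline", var, np.median(base[s], axis=0))
             for s in common if len(ind[s]) and len(base[s])]
    else:
        s = common[0]
        n = min(len(base[s]), len(ind[s]))
        if n < 3:
            return None, None
        A = [SubjectStrideField(f"stride{k}", "induced", var, ind[s][k])
             for k in range(n)]
        B = [SubjectStrideField(f"stride{k}", "baseline", var, base[s][k])
             for k in range(n)]
    if len(A) < 3:
        return None, None
    return A, B


def _write_norm_strides(out: Path, fields):
    rows = []
    for role in ("baseline", "induced"):
        for var, by_subj in sorted(fields[role].items()):
            if not var.startswith("emg_"):
                continue
            for sid, curves in sorted(by_subj.items()):
                for k, c in enumerate(curves):
                    rows.append([var, role, sid, k] + list(c))
    cols = ["variable", "condition", "subject", "stride_index"] + [
        f"node_{i}" for i in range(N_NODES)]
    pd.DataFrame(rows, columns=cols).to_csv(out / "emg_norm_strides.csv", index=False)


def _plot_bands(plot_dir: Path, spm_bands):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir.mkdir(parents=True, exist_ok=True)
    x = np.arange(N_NODES)
    for var, (base, ind, res) in sorted(spm_bands.items()):
        fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 5), sharex=True,
                                       height_ratios=[2, 1])
        for data, color, label in ((base, "tab:blue", "baseline"),
                                   (ind, "tab:red", "induced")):
            curves = np.asarray([c for subj in data.values() for c in subj])
            if curves.size == 0:
                continue
            med = np.median(curves, axis=0)
            sd = curves.std(axis=0)
            ax1.plot(x, med, color=color, label=label)
            ax1.fill_between(x, med - sd, med + sd, color=color, alpha=0.25)
        for c in res.clusters:
            for ax in (ax1, ax2):
                ax.axvspan(c["start_pct"], c["end_pct"], color="0.8", zorder=0)
        ax2.plot(x, res.t_field, "k-")
        ax2.axhline(res.critical_threshold, color="r", ls="--")
        ax2.axhline(-res.critical_threshold, color="r", ls="--")
        ax1.set_title(var)
        ax1.legend(frameon=False, fontsize=8)
        ax2.set_xlabel("% stride")
        ax2.set_ylabel("SPM{t}")
        fig.tight_layout()
        fig.savefig(plot_dir / f"{var}.png", dpi=100)
        plt.close(fig)
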