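"""Batch orchestration: fixture studies, per-trial metric tables, reports.

A study folder is described by a YAML manifest listing the metadata table,
the per-trial trajectory files (each mapped to a known individual and
assay), stimulus geometry, and the chronogram with its clade map.
``run_study`` turns that folder into the metric/approach tables, a group
statistics report and a phylogenetic report, deterministically for a given
manifest and seed.  ``generate_fixture_study`` writes a self-consumable
simulated study in the exact formats the readers expect.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats as wfstats
from .phylo import clade_summaries, estimate_lambda, read_newick
from .simulate import SwimSimConfig, morph_preset, simulate_trajectory
from .stimulus import (StimulusConfig, StimulusKind, compute_stimulation_metrics,
                       detect_approaches)
from .trajectory import (ArenaConfig, Assay, BodyShape, EyeMorph,
                         IndividualRecord, compute_kinematics, fill_gaps,
                         read_trajectory_csv)
from .wall_following import (BELT_SL, EVENT_MIN_SL, compute_wf_metrics,
                             segment_wf_events)

__all__ = [
    "StudyManifest",
    "run_study",
    "generate_fixture_study",
    "trial_metrics_row",
    "SPECIES_BY_MORPH",
    "FIXTURE_CLADES",
    "fixture_chronogram",
]

# The 13 assayed species grouped by gross eye morphology.
SPECIES_BY_MORPH: dict[str, list[str]] = {
    "normal_eyed": ["S_guilinensis", "S_zhenfengensis", "S_longibarbatus",
                    "S_macrophthalmus", "S_oxycephalus", "S_purpureus",
                    "S_maitianheensis"],
    "micro_eyed": ["S_mashanensis", "S_microphthalmus", "S_bicornutus",
                   "S_multipunctatus"],
    "eyeless": ["S_tianlinensis", "S_tianeensis"],
}

# Synthetic clade assignment for the fixture chronogram: four clades with
# the eyeless pair and most stygomorphic species in clade B, surface forms
# dominating A and D (a plausible stand-in, not the published topology).
FIXTURE_CLADES: dict[str, str] = {
    "S_guilinensis": "A", "S_zhenfengensis": "A", "S_maitianheensis": "A",
    "S_tianlinensis": "B", "S_tianeensis": "B", "S_microphthalmus": "B",
    "S_bicornutus": "B",
    "S_macrophthalmus": "C", "S_longibarbatus": "C", "S_mashanensis": "C",
    "S_multipunctatus": "C",
    "S_oxycephalus": "D", "S_purpureus": "D",
}


def fixture_chronogram() -> str:
    """A synthetic ultrametric 13-tip chronogram (root depth 10) with the
    four fixture clades as monophyletic groups."""
    a = "((S_guilinensis:2,S_zhenfengensis:2):2,S_maitianheensis:4):5"
    b = ("(((S_tianlinensis:1.5,S_tianeensis:1.5):1.5,"
         "S_microphthalmus:3):1,S_bicornutus:4):5")
    c = ("(((S_macrophthalmus:1.5,S_longibarbatus:1.5):1.5,"
         "S_mashanensis:3):1,S_multipunctatus:4):4")
    d = "(S_oxycephalus:3,S_purpureus:3):5"
    return f"(({a},{b}):1,({c},{d}):2);"


@dataclass
class StudyManifest:
    """Description of one study folder (all paths relative to ``root``)."""

    root: Path
    metadata: str
    trials: list[dict]            # {file, individual_id, assay}
    tree: str | None = None
    clade_map: str | None = None
    arena: dict = field(default_factory=dict)
    stimulus: dict = field(default_factory=dict)  # per-assay overrides
    seed: int = 0
    output_dir: str = "results"
    belt_sl: float = BELT_SL
    event_min_sl: float = EVENT_MIN_SL
    resting_threshold_cm_s: float = 0.2
    min_mobile_frac: float = 0.10

    @classmethod
    def load(cls, path) -> "StudyManifest":
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(root=path.parent, **doc)

    def save(self, path) -> None:
        doc = {k: v for k, v in self.__dict__.items() if k != "root"}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    def arena_config(self) -> ArenaConfig:
        return ArenaConfig(**self.arena) if self.arena else ArenaConfig()


def load_metadata(path) -> dict[str, IndividualRecord]:
    df = pd.read_csv(path, sep=None, engine="python")
    out = {}
    for _, row in df.iterrows():
        pfl = row.get("pectoral_fin_length_cm")
        out[str(row["individual_id"])] = IndividualRecord(
            individual_id=str(row["individual_id"]),
            species=str(row["species"]),
            eye_morph=EyeMorph(row["eye_morph"]),
            standard_length_cm=float(row["standard_length_cm"]),
            pectoral_fin_length_cm=None if pd.isna(pfl) else float(pfl),
            body_shape=BodyShape(row.get("body_shape", "compressiform")),
            clade=None if pd.isna(row.get("clade")) else str(row["clade"]))
    return out


def _stimulus_for(assay: Assay, arena: ArenaConfig,
                  overrides: dict) -> StimulusConfig | None:
    kind = {Assay.NO_STIMULATION_10MIN: StimulusKind.NONE,
            Assay.LANDMARK_5MIN: StimulusKind.LANDMARK,
            Assay.VIBRATION_3MIN: StimulusKind.VIBRATION}[assay]
    if kind is StimulusKind.NONE:
        return None
    kw = dict(overrides.get(assay.value, {}))
    center = tuple(kw.pop("center_cm", arena.center))
    stim = StimulusConfig(kind=kind, center_cm=center, **kw)
    stim.validate_inside(arena)
    return stim


def trial_metrics_row(traj, arena: ArenaConfig, stimulus: StimulusConfig | None,
                      belt_sl: float = BELT_SL,
                      event_min_sl: float = EVENT_MIN_SL,
                      resting_threshold_cm_s: float = 0.2) -> dict:
    """All indicators for one gap-filled trial, as one flat table row."""
    ind = traj.individual
    sl = ind.standard_length_cm
    k = compute_kinematics(traj, resting_threshold_cm_s=resting_threshold_cm_s)
    testing_time = traj.assay.duration_s
    events = segment_wf_events(traj, k, arena, sl, belt_sl=belt_sl,
                               min_path_sl=event_min_sl)
    wf = compute_wf_metrics(traj, k, events, sl, testing_time)
    row = {
        "individual_id": ind.individual_id, "species": ind.species,
        "eye_morph": ind.eye_morph.value, "clade": ind.clade,
        "assay": traj.assay.value, "standard_length_cm": sl,
        "wf_distance_sl": wf.wf_distance_sl, "wf_frequency": wf.wf_frequency,
        "wf_time_pct": wf.wf_time_pct,
        "wf_resting_time_s": wf.wf_resting_time_s,
        "wf_speed_sl_s": wf.wf_speed_sl_s,
        "wf_max_speed_sl_s": wf.wf_max_speed_sl_s,
    }
    if stimulus is not None:
        s = compute_stimulation_metrics(traj, k, stimulus, sl, testing_time)
        row.update({"s_frequency": s.s_frequency, "s_time_pct": s.s_time_pct,
                    "s_speed_sl_s": s.s_speed_sl_s,
                    "s_max_speed_sl_s": s.s_max_speed_sl_s})
        row["_approaches"] = detect_approaches(traj, k, stimulus, sl)
    return row


def _mobile_time_s(traj, k) -> float:
    total = 0.0
    for seg in traj.segments:
        i0, i1 = seg.start, seg.stop
        if i1 - i0 < 2:
            continue
        dt = np.diff(traj.times_s[i0:i1])
        total += float(dt[~k.resting_mask[i0 + 1:i1]].sum())
    return total


def run_study(manifest: StudyManifest) -> dict:
    """Run every trial of a study and write metric tables plus reports.

    Returns the output tables; writes ``metrics.csv``, ``approaches.csv``,
    ``dropped.csv``, ``stats_report.json`` and ``phylo_report.json`` under
    the manifest's output directory.  Deterministic for fixed inputs.
    """
    root = Path(manifest.root)
    arena = manifest.arena_config()
    individuals = load_metadata(root / manifest.metadata)
    outdir = root / manifest.output_dir
    outdir.mkdir(parents=True, exist_ok=True)

    rows, approach_rows, dropped = [], [], []
    for trial in manifest.trials:
        fname = trial["file"]
        iid = str(trial["individual_id"])
        if iid not in individuals:
            raise ValueError(f"trajectory file {fname!r} maps to unknown "
                             f"individual {iid!r}")
        assay = Assay(trial["assay"])
        ind = individuals[iid]
        traj = read_trajectory_csv(root / fname, arena, ind, assay=assay)
        traj = fill_gaps(traj)
        k = compute_kinematics(
            traj, resting_threshold_cm_s=manifest.resting_threshold_cm_s)
        mobile = _mobile_time_s(traj, k)
        analysed = min(assay.duration_s, traj.duration_s)
        if mobile < manifest.min_mobile_frac * analysed:
            dropped.append({"file": fname, "individual_id": iid,
                            "assay": assay.value,
                            "reason": f"mobile time {mobile:.1f}s below "
                                      f"{manifest.min_mobile_frac:.0%} of "
                                      f"recorded time"})
            continue
        stim = _stimulus_for(assay, arena, manifest.stimulus)
        row = trial_metrics_row(
            traj, arena, stim, belt_sl=manifest.belt_sl,
            event_min_sl=manifest.event_min_sl,
            resting_threshold_cm_s=manifest.resting_threshold_cm_s)
        row["file"] = fname
        for ev in row.pop("_approaches", []):
            approach_rows.append({
                "individual_id": iid, "trial": fname, "order": ev.order,
                "angle_deg": ev.angle_deg, "distance_sl": ev.distance_sl,
                "time_s": ev.time_s})
        rows.append(row)

    metrics = pd.DataFrame(rows)
    approaches = pd.DataFrame(
        approach_rows, columns=["individual_id", "trial", "order",
                                "angle_deg", "distance_sl", "time_s"])
    drops = pd.DataFrame(dropped, columns=["file", "individual_id", "assay",
                                           "reason"])
    fmt = "%.10g"
    metrics.to_csv(outdir / "metrics.csv", index=False, float_format=fmt)
    approaches.to_csv(outdir / "approaches.csv", index=False, float_format=fmt)
    drops.to_csv(outdir / "dropped.csv", index=False)

    stats_report = _stats_report(metrics)
    with open(outdir / "stats_report.json", "w") as fh:
        json.dump(stats_report, fh, indent=1, sort_keys=True)

    phylo_report = _phylo_report(manifest, metrics)
    with open(outdir / "phylo_report.json", "w") as fh:
        json.dump(phylo_report, fh, indent=1, sort_keys=True)

    return {"metrics": metrics, "approaches": approaches, "dropped": drops,
            "stats_report": stats_report, "phylo_report": phylo_report}


WF_INDICATORS = ["wf_distance_sl", "wf_frequency", "wf_time_pct",
                 "wf_resting_time_s", "wf_speed_sl_s", "wf_max_speed_sl_s"]


def _stats_report(metrics: pd.DataFrame) -> dict:
    report: dict = {"group_comparisons": {}, "model_average": None,
                    "group_means": {}}
    if metrics.empty:
        return report
    morphs = [m for m in ("eyeless", "micro_eyed", "normal_eyed")
              if (metrics["eye_morph"] == m).any()]
    for ind in WF_INDICATORS:
        report["group_means"][ind] = {
            m: {"mean": float(metrics.loc[metrics.eye_morph == m, ind].mean()),
                "sd": float(metrics.loc[metrics.eye_morph == m, ind].std(ddof=1)),
                "median": float(metrics.loc[metrics.eye_morph == m, ind].median()),
                "n": int((metrics.eye_morph == m).sum())}
            for m in morphs}
    if len(morphs) >= 2 and all((metrics.eye_morph == m).sum() >= 2
                                for m in morphs):
        for ind in WF_INDICATORS:
            groups = [metrics.loc[metrics.eye_morph == m, ind].to_numpy()
                      for m in morphs]
            kw = wfstats.kruskal_wallis(groups)
            t3 = wfstats.dunnett_t3(groups, labels=morphs)
            report["group_comparisons"][ind] = {
                "kruskal_wallis": {"H": kw.H, "df": kw.df, "p": kw.p_value,
                                   "tie_correction": kw.tie_correction},
                "dunnett_t3": [{"a": c.group_a, "b": c.group_b,
                                "t": c.statistic, "df": c.df,
                                "p_adjusted": c.p_adjusted} for c in t3],
            }
    preds = ["wf_frequency", "wf_time_pct", "wf_max_speed_sl_s",
             "standard_length_cm"]
    if len(metrics) >= 15:
        y = np.round(metrics["wf_distance_sl"]).astype(int).clip(lower=0)
        X = metrics[preds].astype(float)
        X = (X - X.mean()) / X.std(ddof=0).replace(0.0, 1.0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ma = wfstats.model_average_full(y.to_numpy(), X)
            avg = ma.averaged_coefficients
            report["model_average"] = {
                name: {"estimate": float(avg.loc[name, "estimate"]),
                       "adjusted_se": float(avg.loc[name, "adjusted_se"]),
                       "ci_lo": float(avg.loc[name, "ci_lo"]),
                       "ci_hi": float(avg.loc[name, "ci_hi"]),
                       "important": bool(avg.loc[name, "important"])}
                for name in avg.index}
        except (ValueError, RuntimeError) as exc:
            report["model_average"] = {"skipped": str(exc)}
    return report


def _phylo_report(manifest: StudyManifest, metrics: pd.DataFrame) -> dict:
    report: dict = {"lambda": {}, "clades": None}
    if manifest.tree is None or metrics.empty:
        return report
    clade_map = None
    if manifest.clade_map is not None:
        with open(Path(manifest.root) / manifest.clade_map) as fh:
            clade_map = yaml.safe_load(fh)
    phy = read_newick(Path(manifest.root) / manifest.tree, clade_map=clade_map)
    no_stim = metrics[metrics["assay"] == Assay.NO_STIMULATION_10MIN.value]
    if no_stim.empty:
        no_stim = metrics
    species_means = no_stim.groupby("species")[WF_INDICATORS].mean()
    covered = [s for s in phy.tip_labels if s in species_means.index]
    if len(covered) < phy.n_tips and len(covered) >= 4:
        phy = phy.subset(covered)
    for trait in ("wf_distance_sl", "wf_time_pct", "wf_speed_sl_s",
                  "wf_max_speed_sl_s"):
        col = species_means[trait].reindex(phy.tip_labels)
        if col.isna().any() or len(col) < 4 or col.var() == 0:
            report["lambda"][trait] = {"skipped": "insufficient species data"}
            continue
        est = estimate_lambda(phy, col)
        report["lambda"][trait] = {
            "lambda_hat": est.lambda_hat, "sigma2_hat": est.sigma2_hat,
            "log_likelihood": est.log_likelihood, "p_vs_zero": est.lrt_p_vs_zero}
    if clade_map is not None:
        trials = no_stim.copy()
        trials["clade"] = trials["species"].map(clade_map)
        trials = trials.dropna(subset=["clade"])
        if not trials.empty:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cs = clade_summaries(trials, metrics=["wf_distance_sl",
                                                      "wf_time_pct",
                                                      "wf_speed_sl_s"])
            summ = cs["summary"]
            report["clades"] = {
                "summary": {m: {clade: {"mean": float(summ.loc[clade, (m, "mean")]),
                                        "n": int(summ.loc[clade, (m, "count")])}
                                for clade in summ.index}
                            for m in ("wf_distance_sl", "wf_time_pct",
                                      "wf_speed_sl_s")},
                "comparisons": {
                    m: {"kruskal_wallis": {
                        "H": cmp_["kruskal_wallis"].H,
                        "p": cmp_["kruskal_wallis"].p_value}}
                    for m, cmp_ in cs["comparisons"].items()},
            }
    return report


def generate_fixture_study(n_per_morph: int, duration_s: float = 600.0,
                           seed: int = 0, outdir=None,
                           assays: tuple[str, ...] = ("no_stimulation_10min",),
                           ) -> StudyManifest:
    """Write a simulated study folder runnable by :func:`run_study`.

    For each morph, ``n_per_morph`` trials per assay are simulated with the
    morph's preset, cycling through that morph's species.  Writes trajectory
    CSVs, the metadata table, the 13-tip fixture chronogram with clades A-D,
    the clade map and the manifest.
    """
    if n_per_morph < 1:
        raise ValueError("n_per_morph must be >= 1")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "trajectories").mkdir(exist_ok=True)
    arena = ArenaConfig()
    base = np.random.default_rng(seed)
    meta_rows, trials = [], []
    seen: set[str] = set()
    for morph, species_list in SPECIES_BY_MORPH.items():
        for t in range(n_per_morph):
            species = species_list[t % len(species_list)]
            iid = f"{species}_{t // len(species_list) + 1}"
            if iid not in seen:
                seen.add(iid)
                sl = float(np.clip(base.normal(8.4, 1.28), 5.5, 12.0))
                meta_rows.append({
                    "individual_id": iid, "species": species,
                    "eye_morph": morph,
                    "standard_length_cm": round(sl, 2),
                    "pectoral_fin_length_cm": round(sl * 0.22, 2),
                    "body_shape": ("fusiform" if species in
                                   ("S_macrophthalmus", "S_oxycephalus")
                                   else "compressiform"),
                    "clade": FIXTURE_CLADES[species]})
            sl = next(m["standard_length_cm"] for m in meta_rows
                      if m["individual_id"] == iid)
            for assay_name in assays:
                assay = Assay(assay_name)
                trial_seed = int(base.integers(0, 2 ** 31 - 1))
                cfg = morph_preset(morph, duration_s=min(duration_s,
                                                         assay.duration_s),
                                   seed=trial_seed).config
                stim = _stimulus_for(assay, arena, {})
                if stim is not None:
                    cfg = SwimSimConfig(**{**cfg.__dict__, "stim_attraction":
                                           {"eyeless": 1.2, "micro_eyed": 0.7,
                                            "normal_eyed": 0.3}[morph]})
                ind = IndividualRecord(
                    individual_id=iid, species=species,
                    eye_morph=EyeMorph(morph), standard_length_cm=sl)
                traj = simulate_trajectory(cfg, arena, ind, stimulus=stim,
                                           assay=assay)
                fname = f"trajectories/{iid}_{assay.value}_t{t}.csv"
                write_trajectory_csv(traj, outdir / fname)
                trials.append({"file": fname, "individual_id": iid,
                               "assay": assay.value})
    pd.DataFrame(meta_rows).to_csv(outdir / "metadata.csv", index=False)
    (outdir / "tree.nwk").write_text(fixture_chronogram() + "\n")
    with open(outdir / "clade_map.yaml", "w") as fh:
        yaml.safe_dump(FIXTURE_CLADES, fh, sort_keys=True)
    manifest = StudyManifest(root=outdir, metadata="metadata.csv",
                             trials=trials, tree="tree.nwk",
                             clade_map="clade_map.yaml", seed=seed)
    manifest.save(outdir / "manifest.yaml")
    return manifest


def write_trajectory_csv(traj, path) -> None:
    """Write a track in the exact format :func:`read_trajectory_csv` reads."""
    df = pd.DataFrame({
        "frame": np.arange(len(traj)),
        "time_s": traj.times_s,
        "x_cm": traj.positions_cm[:, 0],
        "y_cm": traj.positions_cm[:, 1]})
    df.to_csv(path, index=False, float_format="%.6f")
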