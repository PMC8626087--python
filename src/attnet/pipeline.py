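"""End-to-end orchestration: simulate -> preprocess -> connect -> test.

`run_pipeline` generates a cohort with a configurable connectivity effect
confined to one group x session cell of the attention network, cleans every
run with the censoring-aware pipeline, builds Fisher-z connectivity matrices
for the attention (DVAN) and default-mode (DMN) ROI sets, and runs the
statistical battery: network-mean and edge-level mixed repeated-measures
ANOVAs, per-session one-way ANOVAs, pairwise t-tests, the behavioral
analyses, and the connectivity-behavior regression.  Everything is driven by
one seed; a saved config re-run reproduces identical tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import preprocessing as prep
from . import stats as st
from . import synthetic as syn
from .rois import DEFAULT_ROI_SETS, DMN, DVAN, roi_names


@dataclass
class RunConfig:
    """Fully serializable configuration of a pipeline run."""

    seed: int = 0
    groups: tuple[str, ...] = syn.DEFAULT_GROUPS
    n_per_group: int = 10
    sessions: int = 2
    n_frames: int = 120
    tr: float = 2.0
    ar_coeff: float = 0.4
    base_r_within: float = 0.3
    delta_z: float = 0.3
    target_group: str = "Parietal"
    target_network: str = DVAN
    effect_session: int = 1
    motion_spike_rate: float = 0.02
    motion_spike_amplitude: float = 1.0
    fd_threshold: float = 0.5
    run_discard_mm: float = 3.0
    initial_volumes_dropped: int = 4
    min_retained_seconds: float = 180.0
    low_hz: float = 0.009
    high_hz: float = 0.08
    edge_level: bool = True
    dmn_control: bool = True
    behavior: bool = True
    out_dir: str | None = None

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["groups"] = list(d["groups"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["groups"] = tuple(d.get("groups", syn.DEFAULT_GROUPS))
        return cls(**d)

    def censor_config(self) -> prep.CensorConfig:
        return prep.CensorConfig(
            fd_threshold=self.fd_threshold,
            run_discard_mm=self.run_discard_mm,
            initial_volumes_dropped=self.initial_volumes_dropped,
            min_retained_seconds=self.min_retained_seconds,
        )

    def filter_spec(self) -> prep.FilterSpec:
        return prep.FilterSpec(low_hz=self.low_hz, high_hz=self.high_hz)


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    network_means: pd.DataFrame  # subject, group, session, roi_set, mean_z
    edge_table: pd.DataFrame
    censor_report: pd.DataFrame
    anova_tables: dict[str, st.AnovaTable]
    ttests: dict[str, list[st.TTestResult]]
    regression: st.RegressionResult | None
    behavior: pd.DataFrame | None
    provenance: dict


def _simulate_and_clean_cohort(config: RunConfig, rng: np.random.Generator):
    cohort_spec = syn.CohortSpec(
        groups=config.groups,
        n_per_group=config.n_per_group,
        sessions=config.sessions,
        seed=int(rng.integers(2**31 - 1)),
    )
    cohort = syn.generate_cohort(cohort_spec)
    effect = syn.EffectSpec(
        target_group=config.target_group,
        target_network=config.target_network,
        session_index=config.effect_session,
        delta_z=config.delta_z,
    )
    networks = [DVAN] + ([DMN] if config.dmn_control else [])
    specs_by_network = {}
    for net in networks:
        n_rois = len(DEFAULT_ROI_SETS[net])
        base = syn.BoldSimSpec(
            n_frames=config.n_frames,
            tr=config.tr,
            ar_coeff=config.ar_coeff,
            base_correlation=syn.uniform_network_correlation(n_rois, config.base_r_within),
            network=net,
        )
        specs_by_network[net] = syn.inject_connectivity_effect(base, effect, cohort_spec)
    censor_cfg = config.censor_config()
    filt = config.filter_spec()
    mean_rows, edge_frames, censor_rows = [], [], []
    for _, subj in cohort.iterrows():
        for s in range(config.sessions):
            ses = f"ses-{s + 1}"
            motion, _spikes = syn.simulate_motion(
                config.n_frames,
                spike_rate=config.motion_spike_rate,
                spike_amplitude=config.motion_spike_amplitude,
                seed=rng,
            )
            for net in networks:
                spec = specs_by_network[net][(subj["group"], s)]
                series = syn.simulate_roi_timeseries(
                    spec, roi_names(DEFAULT_ROI_SETS[net]), rng
                )
                result = prep.preprocess_run(
                    series, motion, censor_cfg, filt, rng=rng
                )
                censor_rows.append(
                    {
                        "subject": subj["subject"],
                        "session": ses,
                        "roi_set": net,
                        "excluded": result.excluded,
                        "retained_frames": result.retained_frames,
                        "censored_frames": result.censored_frames,
                    }
                )
                if result.excluded:
                    continue
                cm = conn.correlation_matrix(
                    result.run, subject=subj["subject"], session=ses, roi_set=net
                )
                summ = conn.network_mean(cm)
                mean_rows.append(
                    {
                        "subject": subj["subject"],
                        "group": subj["group"],
                        "session": ses,
                        "roi_set": net,
                        "mean_z": summ.mean_z,
                    }
                )
                edge_frames.append(cm.edge_table().assign(group=subj["group"]))
    return (
        cohort,
        pd.DataFrame(mean_rows),
        pd.concat(edge_frames, ignore_index=True) if edge_frames else pd.DataFrame(),
        pd.DataFrame(censor_rows),
    )


def _complete_subjects(df: pd.DataFrame, sessions: int) -> pd.DataFrame:
    """Keep subjects with data for every session (mixed ANOVA needs balance)."""
    ok = df.groupby("subject")["session"].nunique()
    keep = ok[ok == sessions].index
    return df[df["subject"].isin(keep)]


def run_pipeline(config: RunConfig) -> PipelineResult:
    rng = np.random.default_rng(config.seed)
    cohort, means, edges, censor = _simulate_and_clean_cohort(config, rng)
    anovas: dict[str, st.AnovaTable] = {}
    ttests: dict[str, list[st.TTestResult]] = {}
    networks = [DVAN] + ([DMN] if config.dmn_control else [])
    for net in networks:
        sub = _complete_subjects(
            means[means["roi_set"] == net], config.sessions
        ).rename(columns={"mean_z": "value"})
        if sub.empty:
            continue
        # drop incomplete groups to keep the split-plot design balanced
        n_min = sub.groupby("group")["subject"].nunique().min()
        balanced = []
        for g, gdf in sub.groupby("group"):
            subj_keep = sorted(gdf["subject"].unique())[: int(n_min)]
            balanced.append(gdf[gdf["subject"].isin(subj_keep)])
        sub = pd.concat(balanced, ignore_index=True)
        table, sph = st.mixed_rm_anova(sub, within="session")
        table.notes["sphericity"] = sph
        anovas[f"{net}_network_mixed"] = table
        for ses, sdf in sub.groupby("session"):
            t, hom = st.one_way_anova(sdf["value"].to_numpy(), sdf["group"].to_numpy())
            t.notes["levene"] = hom
            anovas[f"{net}_network_oneway_{ses}"] = t
        last = sub[sub["session"] == f"ses-{config.sessions}"]
        ttests[f"{net}_post_between_groups"] = st.pairwise_ttests(
            last, dv="value", factor="group"
        )
        if config.edge_level and not edges.empty:
            esub = edges[edges["roi_set"] == net].copy()
            esub["unit"] = (
                esub["subject"] + ":" + esub["roi_a"] + ":" + esub["roi_b"]
            )
            esub = esub.rename(columns={"z": "value"})
            ok = esub.groupby("unit")["session"].nunique()
            esub = esub[esub["unit"].isin(ok[ok == config.sessions].index)]
            n_min = esub.groupby("group")["unit"].nunique().min()
            balanced = []
            for g, gdf in esub.groupby("group"):
                keep = sorted(gdf["unit"].unique())[: int(n_min)]
                balanced.append(gdf[gdf["unit"].isin(keep)])
            esub = pd.concat(balanced, ignore_index=True)
            etable, _ = st.mixed_rm_anova(
                esub, subject="unit", within="session"
            )
            etable.notes["non_independent_edges"] = (
                "edge observations within a subject are treated as independent "
                "units, as in the replicated analysis; interpret accordingly"
            )
            anovas[f"{net}_edge_mixed"] = etable
    behavior = None
    regression = None
    if config.behavior:
        behavior = syn.simulate_behavioral_cohort(cohort, seed=rng)
        od = behavior[behavior["task"] == "OD"]
        prepost = od[od["session"].isin(["pre", "post"])].rename(
            columns={"accuracy": "value"}
        )
        table, sph = st.mixed_rm_anova(prepost, within="session")
        anovas["behavior_OD_mixed"] = table
        improvements = (
            od.pivot_table(index=["subject", "group"], columns="session", values="accuracy")
            .reset_index()
            .assign(improvement=lambda d: d["post"] - d["pre"])
        )
        t, hom = st.one_way_anova(
            improvements["improvement"].to_numpy(), improvements["group"].to_numpy()
        )
        anovas["behavior_OD_improvement_oneway"] = t
        ttests["behavior_OD_improvement"] = st.pairwise_ttests(
            improvements.rename(columns={"improvement": "value"}),
            dv="value",
            factor="group",
            correction="bonferroni",
        )
        post_fc = means[
            (means["roi_set"] == DVAN) & (means["session"] == f"ses-{config.sessions}")
        ][["subject", "mean_z"]]
        merged = improvements.merge(post_fc, on="subject")
        if len(merged) >= 3 and merged["mean_z"].std() > 0:
            regression = st.fc_behavior_regression(
                merged["mean_z"].to_numpy(), merged["improvement"].to_numpy()
            )
    provenance = {
        "seed": config.seed,
        "config": {**asdict(config), "groups": list(config.groups)},
        "n_runs_excluded": int(censor["excluded"].sum()),
        "stages": prep.STAGE_ORDER,
    }
    result = PipelineResult(
        cohort=cohort,
        network_means=means,
        edge_table=edges,
        censor_report=censor,
        anova_tables=anovas,
        ttests=ttests,
        regression=regression,
        behavior=behavior,
        provenance=provenance,
    )
    if config.out_dir:
        write_outputs(result, config.out_dir)
    return result


def report_tables(result: PipelineResult) -> pd.DataFrame:
    """One row per ANOVA effect: F, df1, df2 (fractional allowed), p, eta_p2."""
    rows = []
    for name, table in result.anova_tables.items():
        for r in table.rows:
            rows.append(
                {
                    "analysis": name,
                    "effect": r.effect,
                    "F": r.F,
                    "df1": r.df1,
                    "df2": r.df2,
                    "p": r.p,
                    "eta_p2": r.partial_eta_sq,
                    "correction": r.correction,
                }
            )
    return pd.DataFrame(
        rows, columns=["analysis", "effect", "F", "df1", "df2", "p", "eta_p2", "correction"]
    )


def write_outputs(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
    result.network_means.to_csv(out / "network_means.tsv", sep="\t", index=False)
    if not result.edge_table.empty:
        result.edge_table.to_csv(out / "edges.tsv", sep="\t", index=False)
    result.censor_report.to_csv(out / "censor_report.tsv", sep="\t", index=False)
    report_tables(result).to_csv(out / "anova_report.tsv", sep="\t", index=False)
    trows = []
    for name, tests in result.ttests.items():
        for t in tests:
            trows.append(
                {
                    "analysis": name,
                    "comparison": t.label,
                    "t": t.t,
                    "df": t.df,
                    "p": t.p,
                    "p_adjusted": t.p_adjusted,
                    "cohens_d": t.cohens_d,
                    "paired": t.paired,
                }
            )
    pd.DataFrame(
        trows,
        columns=["analysis", "comparison", "t", "df", "p", "p_adjusted", "cohens_d", "paired"],
    ).to_csv(out / "ttest_report.tsv", sep="\t", index=False)
    if result.behavior is not None:
        result.behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)
    if result.regression is not None:
        (out / "regression.json").write_text(json.dumps(asdict(result.regression), indent=2))
    (out / "provenance.json").write_text(json.dumps(result.provenance, indent=2, default=str))
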