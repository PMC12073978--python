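"""Stage-wise orchestration of the full analysis.

Stages: simulate -> score -> stats / graph -> fit -> map -> report.  Each
stage writes its artifacts plus a manifest (config echo, stage seed,
input digests) into the run directory; reruns with the same config are
bit-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import graph as graph_mod
from . import imaging, mapping, sbm, stats, synth, tasks
from .config import ConfigError, RunConfig
from .types import GroundTruth

STAGES = ("simulate", "score", "stats", "graph", "fit", "map", "report")

_DEPENDENCIES = {
    "simulate": (),
    "score": ("simulate",),
    "stats": ("score",),
    "graph": ("simulate",),
    "fit": ("graph",),
    "map": ("graph", "fit"),
    "report": ("fit", "map"),
}


class DependencyError(RuntimeError):
    """A stage's upstream artifacts are missing."""


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(run_dir: Path, stage: str, config: RunConfig, seed: int,
                    artifacts, t0: float) -> None:
    manifest = {
        "stage": stage,
        "seed": seed,
        "config": config.to_dict(),
        "wall_time_s": round(time.time() - t0, 3),
        "artifacts": {
            str(p.relative_to(run_dir)): _digest(p) for p in artifacts
        },
    }
    with open(run_dir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def _require(run_dir: Path, stage: str) -> None:
    for dep in _DEPENDENCIES[stage]:
        if not (run_dir / f"manifest_{dep}.json").exists():
            raise DependencyError(
                f"stage '{stage}' requires stage '{dep}' to run first"
            )


def run_pipeline(config: RunConfig, stages=STAGES, run_dir="run") -> Path:
    """Execute the requested stages in canonical order; returns the run dir."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    for stage in STAGES:
        if stage in stages:
            _require(run_dir, stage)
            t0 = time.time()
            artifacts = _STAGE_FUNCS[stage](config, run_dir)
            _write_manifest(run_dir, stage, config, config.stage_seed(stage), artifacts, t0)
    return run_dir


# ---------------------------------------------------------------------------
# Stage implementations


def _load_scheme(config: RunConfig, run_dir: Path):
    return imaging.read_scheme(
        run_dir / "parcels.nii.gz", run_dir / "parcels.tsv",
        voxel_size_mm=(2.0, 2.0, 2.0),
    )


def _stage_simulate(config: RunConfig, run_dir: Path):
    seed = config.stage_seed("simulate")
    scheme = synth.make_parcel_scheme(config.grid_shape, config.n_parcels, seed=seed)
    substrate = synth.default_substrate(scheme, k=config.substrate_size)
    truth = GroundTruth(
        substrate_parcels=substrate,
        effect_beta=config.effect_beta,
        age_gamma=config.age_gamma,
        noise_sd=config.noise_sd,
        seed=seed,
    )
    masks, cohort = synth.simulate_cohort(
        scheme, truth,
        n_patients=config.n_patients, n_controls=config.n_controls,
        score_ceiling=config.score_ceiling, seed=seed, mu0=config.mu0,
        age_range=config.age_range, size_range=config.lesion_size_range,
    )
    imaging.write_scheme(scheme, run_dir / "parcels.nii.gz", run_dir / "parcels.tsv")
    mask_dir = run_dir / "masks"
    mask_dir.mkdir(exist_ok=True)
    for m in masks:
        imaging.write_mask(m, mask_dir / f"{m.patient_id}.nii.gz", scheme)
    dm = imaging.damage_matrix(masks, scheme)
    dm.to_csv(run_dir / "damage_matrix.tsv", sep="\t")
    labels = [
        imaging.classify_patient(dm.loc[m.patient_id].to_numpy(), scheme)
        for m in masks
    ]
    cohort = cohort.copy()
    lobe = {m.patient_id: g.lobe_group for m, g in zip(masks, labels)}
    cohort["lobe_group"] = [
        lobe.get(pid, "control") for pid in cohort["participant_id"]
    ]
    cohort["group"] = np.where(
        cohort["role"] == "control", "HC", cohort["lobe_group"]
    )
    cohort.to_csv(run_dir / "cohort.tsv", sep="\t", index=False)
    with open(run_dir / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "substrate_parcels": sorted(int(p) for p in substrate),
                "effect_beta": config.effect_beta,
                "age_gamma": config.age_gamma,
                "noise_sd": config.noise_sd,
                "seed": seed,
            },
            fh,
        )
    return [run_dir / "cohort.tsv", run_dir / "damage_matrix.tsv",
            run_dir / "parcels.tsv", run_dir / "ground_truth.json"]


def _stage_score(config: RunConfig, run_dir: Path):
    seed = config.stage_seed("score")
    cohort = pd.read_csv(run_dir / "cohort.tsv", sep="\t")
    out_cols = []
    for bank_fn, name in ((tasks.art_item_bank, "ART"),
                          (tasks.drt_item_bank, "DRT"),
                          (tasks.baseline_item_bank, "baseline")):
        bank = bank_fn()
        log = synth.simulate_responses(cohort, bank, config.ability_scale, seed)
        log.to_csv(run_dir / f"responses_{name}.tsv", sep="\t", index=False)
        summary = tasks.score_summaries(log, bank)
        cohort = cohort.merge(
            summary, left_on="participant_id", right_index=True, how="left"
        )
        out_cols.extend(summary.columns)
    cohort.to_csv(run_dir / "cohort_scored.tsv", sep="\t", index=False)
    return [run_dir / "cohort_scored.tsv"] + [
        run_dir / f"responses_{n}.tsv" for n in ("ART", "DRT", "baseline")
    ]


def _stage_stats(config: RunConfig, run_dir: Path):
    cohort = pd.read_csv(run_dir / "cohort_scored.tsv", sep="\t")
    included = cohort[cohort["group"].isin(["frontal", "posterior", "HC"])]
    score_cols = ["ART_total", "DRT_total", "baseline_total"]
    table = stats.group_table(included, score_cols)
    table.to_csv(run_dir / "behavioural_table.tsv", sep="\t", index=False)
    return [run_dir / "behavioural_table.tsv"]


def _stage_graph(config: RunConfig, run_dir: Path):
    seed = config.stage_seed("graph")
    cohort = pd.read_csv(run_dir / "cohort.tsv", sep="\t")
    dm = pd.read_csv(run_dir / "damage_matrix.tsv", sep="\t", index_col=0)
    dm.columns = dm.columns.astype(int)
    dbin = imaging.binarize_damage(dm, tau=config.tau)
    z = graph_mod.deficit_scores(cohort, "score")
    patients = cohort[cohort["role"] == "patient"]
    z_adj = graph_mod.residualize_age(z.z, patients["age"].to_numpy())
    g_test = graph_mod.build_graph(dbin, z_adj, m_min=config.m_min)
    g_null = graph_mod.permute_null(dbin, z_adj, seed=seed, m_min=config.m_min)
    g_test.write(run_dir / "graph_test.tsv", run_dir / "graph_nodes.tsv")
    g_null.write(run_dir / "graph_null.tsv")
    z_adj.rename("z").to_csv(run_dir / "deficit_z.tsv", sep="\t")
    return [run_dir / "graph_test.tsv", run_dir / "graph_null.tsv",
            run_dir / "graph_nodes.tsv", run_dir / "deficit_z.tsv"]


def _stage_fit(config: RunConfig, run_dir: Path):
    seed = config.stage_seed("fit")
    g_test = graph_mod.LayeredGraph.read(run_dir / "graph_test.tsv", run_dir / "graph_nodes.tsv")
    g_null = graph_mod.LayeredGraph.read(run_dir / "graph_null.tsv", run_dir / "graph_nodes.tsv")
    ed_bins = (
        sbm.quantile_bin_edges(g_test.edges["w_les"].to_numpy(), config.n_bins),
        sbm.quantile_bin_edges(g_test.edges["w_def"].to_numpy(), config.n_bins),
    )
    st = sbm.fit_sbm(g_test, b_max=config.b_max, n_sweeps=config.n_sweeps,
                     seed=seed, n_bins=config.n_bins, bin_edges=ed_bins)
    sn = sbm.fit_sbm(g_null, b_max=config.b_max, n_sweeps=config.n_sweeps,
                     seed=seed, n_bins=config.n_bins, bin_edges=ed_bins)
    comp = sbm.compare_models(st, sn)
    st.membership().to_csv(run_dir / "blocks_test.tsv", sep="\t", index=False)
    summary = {
        "test": st.to_json_summary(),
        "null": sn.to_json_summary(),
        "comparison": {
            "s_test": comp.s_test, "s_null": comp.s_null,
            "delta": comp.delta, "odds_label": comp.odds_label,
        },
        "dendrogram": sbm.merge_dendrogram(g_test, st, n_bins=config.n_bins,
                                           bin_edges=ed_bins),
    }
    for state in (summary["test"], summary["null"]):
        state["config"].pop("dl_trace", None)
    with open(run_dir / "sbm_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return [run_dir / "blocks_test.tsv", run_dir / "sbm_summary.json"]


def _stage_map(config: RunConfig, run_dir: Path):
    seed = config.stage_seed("map")
    scheme = _load_scheme(config, run_dir)
    cohort = pd.read_csv(run_dir / "cohort.tsv", sep="\t")
    dm = pd.read_csv(run_dir / "damage_matrix.tsv", sep="\t", index_col=0)
    dm.columns = dm.columns.astype(int)
    dbin = imaging.binarize_damage(dm, tau=config.tau)
    z_adj = pd.read_csv(run_dir / "deficit_z.tsv", sep="\t", index_col=0)["z"]
    g_test = graph_mod.LayeredGraph.read(run_dir / "graph_test.tsv", run_dir / "graph_nodes.tsv")
    blocks = pd.read_csv(run_dir / "blocks_test.tsv", sep="\t")
    cis = mapping.bootstrap_cis(dbin, z_adj, n_boot=config.n_boot,
                                alpha=config.alpha, seed=seed, m_min=config.m_min)
    perm = mapping.permutation_reference(dbin, z_adj, n_perm=config.n_boot,
                                         alpha=config.alpha, seed=seed + 1,
                                         m_min=config.m_min)
    state = _state_from_membership(blocks)
    nmap = mapping.network_map(g_test, cis.join(perm), state=state,
                               lesion_reference=config.lesion_reference)
    mapping.export_parcel_map(nmap, scheme, run_dir / "deficit_map.nii.gz",
                              table_path=run_dir / "network_map.tsv")
    with open(run_dir / "ground_truth.json") as fh:
        gt = json.load(fh)
    truth = GroundTruth(substrate_parcels=frozenset(gt["substrate_parcels"]),
                        effect_beta=gt["effect_beta"], age_gamma=gt["age_gamma"],
                        noise_sd=gt["noise_sd"], seed=gt["seed"])
    recovery = mapping.substrate_recovery(nmap, truth)
    with open(run_dir / "recovery.json", "w") as fh:
        json.dump(recovery, fh)
    return [run_dir / "network_map.tsv", run_dir / "deficit_map.nii.gz",
            run_dir / "recovery.json"]


class _MembershipState:
    def __init__(self, nodes, partition):
        self.nodes = nodes
        self.partition = partition


def _state_from_membership(blocks: pd.DataFrame):
    return _MembershipState(blocks["node"].to_numpy(), blocks["block"].to_numpy())


def _stage_report(config: RunConfig, run_dir: Path):
    lines = ["# Graph lesion-deficit mapping run report", ""]
    beh = run_dir / "behavioural_table.tsv"
    if beh.exists():
        lines += ["## Behavioural comparisons", "",
                  pd.read_csv(beh, sep="\t").to_string(index=False), ""]
    else:
        lines += ["## Behavioural comparisons", "", "(unavailable: stats stage not run)", ""]
    with open(run_dir / "sbm_summary.json") as fh:
        s = json.load(fh)
    comp = s["comparison"]
    lines += [
        "## Model comparison",
        "",
        f"S_test = {comp['s_test']:.1f} nats; S_null = {comp['s_null']:.1f} nats; "
        f"delta = {comp['delta']:.1f} nats (odds {comp['odds_label']} in favour of test)",
        "",
        f"Dendrogram: {s['dendrogram']}",
        "",
    ]
    nmap = pd.read_csv(run_dir / "network_map.tsv", sep="\t", index_col=0)
    retained = nmap[nmap["retained"].fillna(False)]
    lines += ["## Retained parcels", "",
              retained.to_string() if len(retained) else "(none retained)", ""]
    rec = run_dir / "recovery.json"
    if rec.exists():
        with open(rec) as fh:
            r = json.load(fh)
        lines += ["## Substrate recovery", "",
                  f"Jaccard = {r['jaccard']:.3f}; sensitivity = {r['sensitivity']:.3f}; "
                  f"specificity = {r['specificity']:.3f}", ""]
    report_path = run_dir / "report.md"
    report_path.write_text("\n".join(lines))
    return [report_path]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "score": _stage_score,
    "stats": _stage_stats,
    "graph": _stage_graph,
    "fit": _stage_fit,
    "map": _stage_map,
    "report": _stage_report,
}


def report(run_dir) -> str:
    """Build (or rebuild) the summary report for an existing run directory."""
    run_dir = Path(run_dir)
    _require(run_dir, "report")
    cfg_files = sorted(run_dir.glob("manifest_*.json"))
    with open(cfg_files[0]) as fh:
        config = RunConfig.from_dict(json.load(fh)["config"])
    _stage_report(config, run_dir)
    return (run_dir / "report.md").read_text()
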