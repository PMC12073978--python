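"""Backprojection of edge weights to parcels, bootstrap CIs, retention.

A parcel's deficit strength is the support-weighted mean of the deficit
weights of its incident edges; its lesion strength is the mean lesion
co-occurrence weight of those edges.  Patient-level bootstrap resampling
gives percentile confidence intervals for both; a parcel is retained when
its deficit CI lies wholly above its lesion CI (the two intervals are
disjoint in the impaired direction), separating behaviourally coupled
parcels from ones that are merely frequently co-lesioned.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import imaging
from .graph import DeficitScore, LayeredGraph
from .types import GroundTruth, ParcelScheme


def node_strengths(graph: LayeredGraph) -> pd.DataFrame:
    """Per-parcel deficit and lesion strengths from incident edges.

    deficit_strength(p) = sum over incident edges of support * w_def /
    sum of support;  lesion_strength(p) = mean w_les over incident edges.
    Isolated nodes get NaN strengths and connected=False.
    """
    if graph.n_edges == 0:
        raise ValueError("graph has no edges")
    nodes = np.asarray(graph.nodes, dtype=int)
    pos = {int(n): i for i, n in enumerate(nodes)}
    sup_sum = np.zeros(len(nodes))
    supdef_sum = np.zeros(len(nodes))
    les_sum = np.zeros(len(nodes))
    deg = np.zeros(len(nodes))
    for row in graph.edges.itertuples(index=False):
        for node in (int(row.j), int(row.k)):
            i = pos[node]
            sup_sum[i] += row.support
            supdef_sum[i] += row.support * row.w_def
            les_sum[i] += row.w_les
            deg[i] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        dstr = np.where(sup_sum > 0, supdef_sum / sup_sum, np.nan)
        lstr = np.where(deg > 0, les_sum / deg, np.nan)
    return pd.DataFrame(
        {
            "parcel_id": nodes,
            "deficit_strength": dstr,
            "lesion_strength": lstr,
            "degree": deg.astype(int),
            "connected": deg > 0,
        }
    ).set_index("parcel_id")


def _strengths_fast(vals: np.ndarray, z: np.ndarray, m_min: int):
    """Vectorised node strengths straight from a binary damage matrix."""
    n = vals.shape[0]
    support = vals.T @ vals
    zsum = vals.T @ (vals * z[:, None])
    np.fill_diagonal(support, 0.0)
    np.fill_diagonal(zsum, 0.0)
    keep = support >= m_min
    sup = np.where(keep, support, 0.0)
    zs = np.where(keep, zsum, 0.0)
    sup_row = sup.sum(axis=1)
    deg = keep.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dstr = np.where(sup_row > 0, zs.sum(axis=1) / np.maximum(sup_row, 1e-300), np.nan)
        lstr = np.where(deg > 0, (sup / n).sum(axis=1) / np.maximum(deg, 1), np.nan)
    return dstr, lstr


def bootstrap_cis(
    damage_bin: pd.DataFrame,
    z: DeficitScore | pd.Series,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    m_min: int = 2,
) -> pd.DataFrame:
    """Patient-bootstrap percentile CIs for both node strengths.

    Patients are resampled with replacement; the graph and node strengths
    are recomputed per replicate.  A parcel missing from a replicate (never
    co-damaged there) contributes nothing to its CI; the number of usable
    replicates is reported per parcel.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    zs = (z.z if isinstance(z, DeficitScore) else z).to_numpy(dtype=float)
    vals = damage_bin.to_numpy(dtype=float)
    n, p = vals.shape
    rng = np.random.default_rng(seed)
    dstr_rep = np.empty((n_boot, p))
    lstr_rep = np.empty((n_boot, p))
    for it in range(n_boot):
        idx = rng.integers(0, n, size=n)
        dstr_rep[it], lstr_rep[it] = _strengths_fast(vals[idx], zs[idx], m_min)
    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    n_ok = np.sum(~np.isnan(dstr_rep), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN parcels
        out = pd.DataFrame(
            {
                "def_ci_low": np.nanpercentile(dstr_rep, lo_q, axis=0),
                "def_ci_high": np.nanpercentile(dstr_rep, hi_q, axis=0),
                "les_ci_low": np.nanpercentile(lstr_rep, lo_q, axis=0),
                "les_ci_high": np.nanpercentile(lstr_rep, hi_q, axis=0),
                "n_boot_ok": n_ok,
            },
            index=pd.Index(np.asarray(damage_bin.columns, dtype=int), name="parcel_id"),
        )
    return out


def permutation_reference(
    damage_bin: pd.DataFrame,
    z: DeficitScore | pd.Series,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    m_min: int = 2,
) -> pd.DataFrame:
    """Per-parcel interval of deficit strength under behaviour permutation.

    Shuffling z across patients preserves the lesion layer exactly, so the
    resulting spread of node deficit strengths is the deficit weight
    attributable to lesion anatomy alone — the reference against which an
    observed deficit strength must stand out.
    """
    zs = (z.z if isinstance(z, DeficitScore) else z).to_numpy(dtype=float)
    vals = damage_bin.to_numpy(dtype=float)
    n, p = vals.shape
    rng = np.random.default_rng(seed)
    dstr_rep = np.empty((n_perm, p))
    for it in range(n_perm):
        dstr_rep[it], _ = _strengths_fast(vals, zs[rng.permutation(n)], m_min)
    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN parcels
        out = pd.DataFrame(
            {
                "perm_ci_low": np.nanpercentile(dstr_rep, lo_q, axis=0),
                "perm_ci_high": np.nanpercentile(dstr_rep, hi_q, axis=0),
                "n_perm_ok": np.sum(~np.isnan(dstr_rep), axis=0),
            },
            index=pd.Index(np.asarray(damage_bin.columns, dtype=int), name="parcel_id"),
        )
    return out


def network_map(
    graph: LayeredGraph,
    cis: pd.DataFrame,
    state=None,
    lesion_reference: str = "permutation",
) -> pd.DataFrame:
    """Assemble the parcel-level map: strengths, CIs, retention, community.

    ``lesion_reference`` selects the comparison interval for retention:
    ``permutation`` (default) uses the behaviour-permutation interval of the
    same parcel's deficit strength (requires ``perm_ci_*`` columns in
    ``cis``); ``per_node`` uses the parcel's lesion-strength CI; ``global``
    uses the 2.5-97.5 percentile interval of lesion strengths across parcels.
    """
    strengths = node_strengths(graph)
    out = strengths.join(cis, how="left")
    if state is not None:
        blocks = pd.Series(state.partition, index=np.asarray(state.nodes, dtype=int))
        out["community"] = blocks.reindex(out.index)
    else:
        out["community"] = np.nan
    out = retention_rule(out, lesion_reference=lesion_reference)
    return out


def retention_rule(map_df: pd.DataFrame, lesion_reference: str = "permutation") -> pd.DataFrame:
    """Flag parcels whose deficit CI clears the lesion-weight reference CI.

    retained(p) = True iff both intervals exist and def_ci_low(p) lies above
    the upper end of the reference interval — the intervals are disjoint with
    the deficit interval above.  The reference is the permutation interval of
    the parcel's deficit strength (default), its lesion-strength CI, or the
    global lesion-strength interval.  Parcels lacking a CI are marked not
    retained with a reason.
    """
    out = map_df.copy()
    if lesion_reference == "permutation":
        les_hi = out["perm_ci_high"]
    elif lesion_reference == "per_node":
        les_hi = out["les_ci_high"]
    elif lesion_reference == "global":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            les_hi = pd.Series(
                np.nanpercentile(out["lesion_strength"].to_numpy(dtype=float), 97.5),
                index=out.index,
            )
    else:
        raise ValueError(
            "lesion_reference must be 'permutation', 'per_node' or 'global'"
        )
    have = (
        out[["def_ci_low", "def_ci_high"]].notna().all(axis=1)
        & les_hi.notna()
    )
    out["retained"] = have & (out["def_ci_low"] > les_hi)
    out["retention_reason"] = np.where(
        ~have, "missing CI", np.where(out["retained"], "deficit CI above lesion CI", "CIs overlap or reversed")
    )
    return out


def substrate_recovery(map_df: pd.DataFrame, truth: GroundTruth) -> dict:
    """Jaccard / sensitivity / specificity of retained parcels vs the substrate."""
    retained = set(map_df.index[map_df["retained"].fillna(False)])
    substrate = set(int(p) for p in truth.substrate_parcels)
    all_parcels = set(int(p) for p in map_df.index)
    inter = retained & substrate
    union = retained | substrate
    tn = all_parcels - union
    jaccard = len(inter) / len(union) if union else 1.0
    sens = len(inter) / len(substrate) if substrate else float("nan")
    neg = all_parcels - substrate
    spec = len(tn) / len(neg) if neg else float("nan")
    return {"jaccard": jaccard, "sensitivity": sens, "specificity": spec}


def export_parcel_map(map_df: pd.DataFrame, scheme: ParcelScheme, path, table_path=None):
    """Write the retained deficit-strength map as a parcel-constant volume.

    Voxels of retained parcels carry that parcel's deficit strength; all
    other voxels are zero.  A side-car table with every map field accompanies
    the volume when ``table_path`` is given.
    """
    vol = np.zeros(scheme.grid_shape, dtype=np.float32)
    for pid, row in map_df.iterrows():
        if bool(row.get("retained", False)) and np.isfinite(row["deficit_strength"]):
            vol[scheme.labels == int(pid)] = row["deficit_strength"]
    try:
        imaging.write_map(vol, path, scheme)
    except OSError as exc:
        raise OSError(f"failed writing parcel map to {path}: {exc}") from exc
    if table_path is not None:
        map_df.to_csv(table_path, sep="\t")
    return vol


def community_summary(map_df: pd.DataFrame) -> pd.DataFrame:
    """Retained-community table: block id, member parcels, mean strengths."""
    ret = map_df[map_df["retained"].fillna(False)]
    if ret.empty or ret["community"].isna().all():
        return pd.DataFrame(
            columns=["community", "n_parcels", "parcels", "mean_deficit", "mean_lesion"]
        )
    rows = []
    for block, grp in ret.groupby("community"):
        rows.append(
            dict(
                community=int(block),
                n_parcels=len(grp),
                parcels=",".join(str(int(i)) for i in grp.index),
                mean_deficit=float(grp["deficit_strength"].mean()),
                mean_lesion=float(grp["lesion_strength"].mean()),
            )
        )
    return pd.DataFrame(rows)
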