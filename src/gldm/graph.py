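"""Layered lesion-deficit graph construction.

Nodes are parcels; an edge joins two parcels co-damaged in at least
``m_min`` patients and carries two weight channels: a lesion layer
``w_les = support / n_patients`` (co-occurrence frequency) and a deficit
layer ``w_def`` = mean healthy-control-anchored deficit z over the
co-damaged patients.  The behaviour-permuted null graph shuffles z across
patients before computing ``w_def``, destroying lesion-behaviour coupling
while preserving the lesion layer exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ReferenceError_(ValueError):
    """Invalid healthy-control reference moments."""


class CoverageError(ValueError):
    """Damage too sparse to build any edge."""


@dataclass(frozen=True)
class DeficitScore:
    """Per-patient deficit in healthy-control SD units (higher = worse)."""

    z: pd.Series
    direction: str = "higher = worse"


@dataclass
class LayeredGraph:
    """Parcel graph with lesion and deficit edge channels.

    ``edges`` columns: j, k (parcel ids, j < k), support (co-damaged patient
    count), w_les, w_def.
    """

    nodes: np.ndarray
    edges: pd.DataFrame
    n_patients: int

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_signature(self) -> frozenset:
        return frozenset(zip(self.edges["j"].astype(int), self.edges["k"].astype(int)))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(int(n) for n in self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(
                int(row.j), int(row.k),
                support=int(row.support), w_les=row.w_les, w_def=row.w_def,
            )
        return g

    def write(self, edge_path, node_path=None) -> None:
        self.edges.to_csv(edge_path, sep="\t", index=False)
        if node_path is not None:
            pd.DataFrame({"parcel_id": self.nodes}).assign(
                n_patients=self.n_patients
            ).to_csv(node_path, sep="\t", index=False)

    @classmethod
    def read(cls, edge_path, node_path) -> "LayeredGraph":
        edges = pd.read_csv(edge_path, sep="\t")
        nodes_tab = pd.read_csv(node_path, sep="\t")
        return cls(
            nodes=nodes_tab["parcel_id"].to_numpy(),
            edges=edges,
            n_patients=int(nodes_tab["n_patients"].iloc[0]),
        )


def deficit_scores(
    cohort: pd.DataFrame,
    score_column: str = "score",
    hc_reference: tuple | None = None,
) -> DeficitScore:
    """Deficit z per patient against healthy-control reference moments.

    z_i = (hc_mean - score_i) / hc_sd, so positive z means impairment.  If
    ``hc_reference`` is None the moments are estimated from the cohort rows
    with role == "control".
    """
    if hc_reference is None:
        hc = cohort.loc[cohort["role"] == "control", score_column]
        if len(hc) < 2:
            raise ReferenceError_("need >= 2 controls to estimate reference moments")
        hc_reference = (float(hc.mean()), float(hc.std(ddof=1)))
    hc_mean, hc_sd = hc_reference
    if hc_sd <= 0:
        raise ReferenceError_("healthy-control SD must be positive")
    patients = cohort[cohort["role"] == "patient"] if "role" in cohort else cohort
    z = (hc_mean - patients[score_column]) / hc_sd
    z.index = patients["participant_id"].to_numpy()
    if not np.isfinite(z).all():
        raise ValueError("non-finite deficit scores")
    return DeficitScore(z=z)


def residualize_age(z: pd.Series, age) -> pd.Series:
    """Remove the linear age trend from z (nuisance adjustment).

    Fits z ~ age by least squares over patients and subtracts the slope
    component, preserving the mean level of z.
    """
    age = np.asarray(age, dtype=float)
    zc = z.to_numpy(dtype=float)
    ac = age - age.mean()
    denom = float(ac @ ac)
    slope = float(ac @ (zc - zc.mean())) / denom if denom > 0 else 0.0
    out = pd.Series(zc - slope * ac, index=z.index, name=z.name)
    return out


def _cooccurrence(damage_values: np.ndarray, z_values: np.ndarray):
    """Support and z-sum matrices from a binary patients x parcels matrix."""
    B = damage_values.astype(float)
    support = B.T @ B
    zsum = B.T @ (B * z_values[:, None])
    np.fill_diagonal(support, 0.0)
    np.fill_diagonal(zsum, 0.0)
    return support, zsum


def build_graph(
    damage_bin: pd.DataFrame, z: DeficitScore | pd.Series, m_min: int = 2
) -> LayeredGraph:
    """Build the layered graph from binarized damage and deficit scores.

    For each parcel pair (j, k): support = number of patients with both
    damaged; the edge is kept iff support >= m_min, with
    w_les = support / n_patients and w_def = mean z over co-damaged patients.
    """
    zs = z.z if isinstance(z, DeficitScore) else z
    if len(zs) != len(damage_bin):
        raise ValueError("damage matrix rows must align with deficit scores")
    vals = damage_bin.to_numpy(dtype=float)
    n = vals.shape[0]
    support, zsum = _cooccurrence(vals, zs.to_numpy(dtype=float))
    parcel_ids = np.asarray(damage_bin.columns, dtype=int)
    jj, kk = np.triu_indices(vals.shape[1], k=1)
    keep = support[jj, kk] >= m_min
    if not keep.any():
        per_patient = vals.sum(axis=1)
        raise CoverageError(
            "no parcel pair is co-damaged in >= "
            f"{m_min} patients (mean damaged parcels/patient = {per_patient.mean():.2f})"
        )
    jj, kk = jj[keep], kk[keep]
    sup = support[jj, kk]
    edges = pd.DataFrame(
        {
            "j": parcel_ids[jj],
            "k": parcel_ids[kk],
            "support": sup.astype(int),
            "w_les": sup / n,
            "w_def": zsum[jj, kk] / sup,
        }
    )
    # isolated parcels carry no co-occurrence information and would only
    # inflate the partition prior downstream; they are dropped here and
    # reported as unevaluated by the mapping stage
    nodes = np.unique(edges[["j", "k"]].to_numpy())
    return LayeredGraph(nodes=nodes, edges=edges, n_patients=n)


def permute_null(
    damage_bin: pd.DataFrame,
    z: DeficitScore | pd.Series,
    seed: int,
    m_min: int = 2,
    permutation: np.ndarray | None = None,
) -> LayeredGraph:
    """Behaviour-permuted null graph: shuffle z across patients, rebuild.

    The lesion layer (edge set, support, w_les) is identical to the test
    graph by construction; only w_def changes.
    """
    zs = (z.z if isinstance(z, DeficitScore) else z).copy()
    if permutation is None:
        rng = np.random.default_rng(seed)
        permutation = rng.permutation(len(zs))
    znull = pd.Series(zs.to_numpy()[permutation], index=zs.index)
    return build_graph(damage_bin, znull, m_min=m_min)
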