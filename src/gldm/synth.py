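"""Synthetic lesion-cohort generator.

Emulates the data a focal-lesion study of reasoning collects: a parcellated
brain grid, unilateral face-connected lesions whose volumes span a wide
(log-uniform) range, a hidden deficit substrate in right frontal cortex, a
bounded percent-correct behavioural score depressed by substrate damage and
by age, and item-level response logs generated from each participant's
latent score.

All draws are seeded; the generator is bit-reproducible for a fixed seed and
configuration.  The per-participant noise term ``epsilon`` is emitted in the
cohort table so the score formula can be re-checked independently.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pandas as pd
from scipy.special import expit

from . import imaging
from .types import FACE_NEIGHBOURS, GroundTruth, LesionMask, ParcelScheme, SizingError

DEFAULT_N_PATIENTS = 247
DEFAULT_N_CONTROLS = 81
DEFAULT_MU0 = 80.0
DEFAULT_AGE_RANGE = (20.0, 75.0)
DEFAULT_SIZE_RANGE = (0.01, 0.15)  # lesion volume as fraction of hemisphere


# ---------------------------------------------------------------------------
# Parcel scheme


def make_parcel_scheme(
    grid_shape, n_parcels: int, seed: int, voxel_size_mm=(2.0, 2.0, 2.0),
    n_lloyd: int = 4,
) -> ParcelScheme:
    """Partition a grid into face-connected parcels, split evenly by hemisphere.

    The sagittal axis is axis 0 and must have even extent so the midplane
    falls between voxel columns; each hemisphere is partitioned by seeded
    multi-source breadth-first growth (a grid Voronoi tessellation), which
    guarantees non-empty, face-connected, disjoint parcels covering the
    hemisphere.  ``n_lloyd`` rounds of Lloyd relaxation (re-seeding each
    parcel at the voxel nearest its centroid) even out parcel volumes, as
    anatomical parcellations do.  Parcels whose centroid lies in the anterior
    half (low axis-1 coordinates) are labelled frontal, the rest posterior.
    """
    nx, ny, nz = grid_shape
    if nx % 2:
        raise ValueError("sagittal extent (axis 0) must be even")
    if n_parcels < 4:
        raise SizingError("need at least 4 parcels")
    if n_parcels % 2:
        raise SizingError("n_parcels must be even to split across hemispheres")
    per_hemi = n_parcels // 2
    hemi_vox = (nx // 2) * ny * nz
    if per_hemi > hemi_vox:
        raise SizingError(
            f"{n_parcels} parcels cannot fit in a grid of {2 * hemi_vox} voxels"
        )
    rng = np.random.default_rng(seed)
    labels = np.zeros(grid_shape, dtype=np.int32)
    hemisphere = []
    for hemi_idx, (side, x0) in enumerate((("left", 0), ("right", nx // 2))):
        offset = hemi_idx * per_hemi
        shape = (nx // 2, ny, nz)
        flat_seeds = rng.choice(hemi_vox, size=per_hemi, replace=False)
        seeds = np.column_stack(np.unravel_index(flat_seeds, shape))
        sub = _voronoi_grow(shape, seeds)
        for _ in range(n_lloyd):
            seeds = _centroid_seeds(sub, per_hemi)
            sub = _voronoi_grow(shape, seeds)
        labels[x0 : x0 + nx // 2] = sub + offset
        hemisphere.extend([side] * per_hemi)
    # lobe from anterior/posterior centroid split on axis 1
    ys = np.indices(grid_shape)[1]
    centroid_y = np.array(
        [ys[labels == p].mean() for p in range(1, n_parcels + 1)]
    )
    lobe = tuple(
        "frontal" if cy < (ny - 1) / 2 else "posterior" for cy in centroid_y
    )
    scheme = ParcelScheme(
        labels=labels,
        hemisphere=tuple(hemisphere),
        lobe=lobe,
        voxel_size_mm=tuple(voxel_size_mm),
    )
    scheme.validate()
    return scheme


def _voronoi_grow(shape, seeds: np.ndarray) -> np.ndarray:
    """Multi-source BFS labelling: voxel -> 1-based index of the BFS-nearest seed."""
    labels = np.zeros(shape, dtype=np.int32)
    queue = deque()
    for i, s in enumerate(seeds, start=1):
        labels[tuple(s)] = i
        queue.append(tuple(s))
    dims = np.array(shape)
    while queue:
        v = queue.popleft()
        lab = labels[v]
        for d in FACE_NEIGHBOURS:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if (
                0 <= w[0] < dims[0]
                and 0 <= w[1] < dims[1]
                and 0 <= w[2] < dims[2]
                and labels[w] == 0
            ):
                labels[w] = lab
                queue.append(w)
    return labels


def _centroid_seeds(labels: np.ndarray, n: int) -> np.ndarray:
    """One seed per parcel: the member voxel nearest the parcel centroid."""
    coords = np.indices(labels.shape).reshape(3, -1).T
    flat = labels.ravel()
    seeds = np.empty((n, 3), dtype=np.int64)
    for p in range(1, n + 1):
        member = coords[flat == p]
        centroid = member.mean(axis=0)
        seeds[p - 1] = member[np.argmin(((member - centroid) ** 2).sum(axis=1))]
    return seeds


def parcel_adjacency(scheme: ParcelScheme):
    """networkx graph of parcels sharing a voxel face."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(scheme.parcel_ids)
    lab = scheme.labels
    for axis in range(3):
        a = np.moveaxis(lab, axis, 0)[:-1]
        b = np.moveaxis(lab, axis, 0)[1:]
        diff = a != b
        pairs = np.unique(
            np.sort(np.column_stack([a[diff], b[diff]]), axis=1), axis=0
        )
        for j, k in pairs:
            if j > 0 and k > 0:
                g.add_edge(int(j), int(k))
    return g


def default_substrate(scheme: ParcelScheme, k: int = 2) -> frozenset:
    """A contiguous set of k right frontal parcels (the simulated substrate).

    Deterministic: starts from the right frontal parcel nearest the centroid
    of the right frontal territory (a typical mid-prefrontal locus rather
    than a pole extremity) and grows along the parcel adjacency graph,
    preferring frontal parcels close to that centroid.
    """
    adj = parcel_adjacency(scheme)
    hemis = np.asarray(scheme.hemisphere)
    lobes = np.asarray(scheme.lobe)
    right_frontal = [
        int(p)
        for p in scheme.parcel_ids
        if hemis[p - 1] == "right" and lobes[p - 1] == "frontal"
    ]
    if not right_frontal:
        raise SizingError("scheme has no right frontal parcels")
    grid = np.indices(scheme.grid_shape)
    centroid = {
        int(p): np.array([g[scheme.labels == p].mean() for g in grid])
        for p in scheme.parcel_ids
        if hemis[p - 1] == "right"
    }
    region_centre = np.mean([centroid[p] for p in right_frontal], axis=0)

    def dist(p):
        return float(np.linalg.norm(centroid[p] - region_centre))

    start = min(right_frontal, key=lambda p: (dist(p), p))
    chosen = [start]
    while len(chosen) < k:
        frontier = sorted(
            {
                int(n)
                for c in chosen
                for n in adj.neighbors(c)
                if n not in chosen and hemis[n - 1] == "right"
            },
            key=lambda p: (lobes[p - 1] != "frontal", dist(p), p),
        )
        if not frontier:
            break
        chosen.append(frontier[0])
    return frozenset(chosen)


# ---------------------------------------------------------------------------
# Lesions


def sample_lesion(
    scheme: ParcelScheme,
    side: str,
    target_volume_vox: int,
    seed: int,
    patient_id="lesion",
    irregularity: float = 0.5,
    start_region: str | None = None,
) -> LesionMask:
    """Region-grow a face-connected blob of exactly ``target_volume_vox`` voxels.

    Growth starts at a random voxel of the requested hemisphere and annexes
    frontier voxels in order of noisy distance from the start: each voxel's
    priority is its Euclidean distance from the seed multiplied by
    ``1 + irregularity * U[0, 1)``.  The result is a bulky, roughly
    ball-shaped mass with a rough boundary — tumour/stroke-like — confined to
    one hemisphere, face-connected by construction.  ``start_region``
    optionally restricts the growth origin (not the grown mass) to the
    anterior (``"frontal"``) or posterior half of the hemisphere, so cohorts
    can reproduce the anterior-weighted lesion distributions of tumour/stroke
    case series.
    """
    hemi = scheme.hemisphere_mask(side)
    hemi_size = int(hemi.sum())
    if not 1 <= target_volume_vox <= hemi_size:
        raise SizingError(
            f"target volume {target_volume_vox} outside [1, {hemi_size}]"
        )
    if irregularity < 0:
        raise ValueError("irregularity must be >= 0")
    import heapq

    rng = np.random.default_rng(seed)
    start_mask = hemi
    if start_region is not None:
        ny = scheme.grid_shape[1]
        region = np.zeros(scheme.grid_shape, dtype=bool)
        if start_region == "frontal":
            region[:, : ny // 2] = True
        elif start_region == "posterior":
            region[:, ny // 2 :] = True
        else:
            raise ValueError(f"unknown start_region {start_region!r}")
        start_mask = hemi & region
    coords = np.argwhere(start_mask)
    start = tuple(int(c) for c in coords[rng.integers(len(coords))])
    dims = scheme.grid_shape
    vol = np.zeros(dims, dtype=bool)
    seen = np.zeros(dims, dtype=bool)
    heap = [(0.0, start)]
    seen[start] = True
    n = 0
    while n < target_volume_vox:
        _, v = heapq.heappop(heap)
        vol[v] = True
        n += 1
        for d in FACE_NEIGHBOURS:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if (
                0 <= w[0] < dims[0]
                and 0 <= w[1] < dims[1]
                and 0 <= w[2] < dims[2]
                and hemi[w]
                and not seen[w]
            ):
                seen[w] = True
                dist = np.sqrt(
                    (w[0] - start[0]) ** 2
                    + (w[1] - start[1]) ** 2
                    + (w[2] - start[2]) ** 2
                )
                prio = dist * (1.0 + irregularity * rng.random())
                heapq.heappush(heap, (prio, w))
    return LesionMask(volume=vol, patient_id=str(patient_id))


# ---------------------------------------------------------------------------
# Cohort


def simulate_cohort(
    scheme: ParcelScheme,
    truth: GroundTruth,
    n_patients: int = DEFAULT_N_PATIENTS,
    n_controls: int = DEFAULT_N_CONTROLS,
    score_ceiling: float = 100.0,
    seed: int = 0,
    mu0: float = DEFAULT_MU0,
    age_range=DEFAULT_AGE_RANGE,
    size_range=DEFAULT_SIZE_RANGE,
    p_right: float = 0.55,
    p_frontal: float = 0.58,
):
    """Simulate lesions and behavioural scores for a patient + control cohort.

    Each patient receives one unilateral lesion (side Bernoulli(p_right),
    growth origin anterior with probability ``p_frontal``, volume log-uniform
    between ``size_range`` fractions of the hemisphere); the default side and
    lobe mixes mirror the composition of focal tumour/stroke case series,
    which are right- and frontally weighted.  The score model is

        score_i = clamp(mu0 - beta * load_i - gamma * (age_i - mean age)
                        + eps_i, 0, ceiling)

    with ``load_i`` the mean damage fraction over the substrate parcels,
    ``eps_i ~ Normal(0, noise_sd)`` and mean age taken over the whole cohort.
    Controls carry no lesion and load 0.

    Returns ``(masks, cohort)`` where ``cohort`` is a DataFrame with columns
    participant_id, role, age, side, lesion_volume_vox, substrate_load,
    epsilon, score.
    """
    substrate = sorted(truth.substrate_parcels)
    if not set(substrate) <= set(int(p) for p in scheme.parcel_ids):
        raise ValueError("substrate parcels not in scheme")
    rng = np.random.default_rng(seed)
    n_total = n_patients + n_controls
    ages = rng.uniform(age_range[0], age_range[1], size=n_total)
    eps = rng.normal(0.0, truth.noise_sd, size=n_total) if truth.noise_sd > 0 else np.zeros(n_total)
    hemi_size = int(scheme.hemisphere_mask("left").sum())
    sides = np.where(rng.random(n_patients) < p_right, "right", "left")
    regions = np.where(rng.random(n_patients) < p_frontal, "frontal", "posterior")
    log_lo, log_hi = np.log(size_range[0]), np.log(size_range[1])
    frac = np.exp(rng.uniform(log_lo, log_hi, size=n_patients))
    volumes = np.maximum(1, np.round(frac * hemi_size)).astype(int)
    lesion_seeds = rng.integers(0, 2**31 - 1, size=n_patients)

    masks, loads, vol_out = [], [], []
    sub_idx = np.array(substrate) - 1
    for i in range(n_patients):
        pid = f"P{i + 1:04d}"
        mask = sample_lesion(
            scheme, sides[i], int(volumes[i]), int(lesion_seeds[i]), patient_id=pid,
            start_region=regions[i],
        )
        fr = imaging.damage_fractions(mask, scheme)
        masks.append(mask)
        loads.append(float(fr[sub_idx].mean()))
        vol_out.append(mask.n_voxels)

    mean_age = float(ages.mean())
    records = []
    for i in range(n_patients):
        records.append(
            dict(
                participant_id=masks[i].patient_id,
                role="patient",
                age=ages[i],
                side=sides[i],
                lesion_volume_vox=vol_out[i],
                substrate_load=loads[i],
                epsilon=eps[i],
            )
        )
    for j in range(n_controls):
        records.append(
            dict(
                participant_id=f"C{j + 1:04d}",
                role="control",
                age=ages[n_patients + j],
                side="none",
                lesion_volume_vox=0,
                substrate_load=0.0,
                epsilon=eps[n_patients + j],
            )
        )
    cohort = pd.DataFrame.from_records(records)
    raw = (
        mu0
        - truth.effect_beta * cohort["substrate_load"]
        - truth.age_gamma * (cohort["age"] - mean_age)
        + cohort["epsilon"]
    )
    cohort["score"] = np.clip(raw, 0.0, score_ceiling)
    return masks, cohort


# ---------------------------------------------------------------------------
# Item-level responses


def simulate_responses(
    cohort: pd.DataFrame, item_bank: pd.DataFrame, ability_scale: float, seed: int
) -> pd.DataFrame:
    """Bernoulli item responses from a logistic ability model.

    P(correct on item q) = logistic(ability_scale * (score_i / 100 -
    difficulty_q)).  One row per participant x item.
    """
    if len(item_bank) == 0:
        raise ValueError("empty item bank")
    if not cohort["score"].between(0, 100).all():
        raise ValueError("cohort scores must lie in [0, 100]")
    rng = np.random.default_rng(seed)
    ability = cohort["score"].to_numpy() / 100.0
    diff = item_bank["difficulty_q"].to_numpy()
    prob = expit(ability_scale * (ability[:, None] - diff[None, :]))
    correct = (rng.random(prob.shape) < prob).astype(np.int8)
    n, m = prob.shape
    return pd.DataFrame(
        {
            "participant_id": np.repeat(cohort["participant_id"].to_numpy(), m),
            "item_id": np.tile(item_bank["item_id"].to_numpy(), n),
            "correct": correct.ravel(),
        }
    )


def response_probabilities(
    cohort: pd.DataFrame, item_bank: pd.DataFrame, ability_scale: float
) -> np.ndarray:
    """The participant x item success-probability matrix of the response model."""
    ability = cohort["score"].to_numpy() / 100.0
    diff = item_bank["difficulty_q"].to_numpy()
    return expit(ability_scale * (ability[:, None] - diff[None, :]))
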