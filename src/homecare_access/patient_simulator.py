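"""Hypothetical patient generation on the population mesh.

Each municipality's patient count (from the claims analysis) is allocated
to that municipality's mesh cells proportionally to the cell population
aged >=75, then each patient is placed uniformly at random inside its
cell's square. Repeating the whole process over independent trials
captures the locational uncertainty of patients known only at mesh
resolution.

Seed discipline: one master seed; the random stream for each
(trial, municipality) pair is derived deterministically from it, so adding
or reordering municipalities does not perturb the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geodata_model import MeshCell, StudyRegion

ALLOCATION_MODES = ("multinomial", "largest_remainder")

PATIENT_COLUMNS = ["id", "trial", "municipality_id", "mesh_id", "x", "y"]


class AllocationError(ValueError):
    """Patients requested for a municipality with no populated mesh cells."""


@dataclass(frozen=True)
class PatientPoint:
    """One hypothetical patient location in one trial."""

    id: str
    trial: int
    municipality_id: str
    mesh_id: str
    x: float
    y: float


def allocate_to_meshes(n_m: int, mesh_populations: Sequence[int] | np.ndarray,
                       mode: str = "multinomial",
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Allocate ``n_m`` patients over mesh cells proportionally to population.

    ``multinomial`` draws counts with probabilities ``pop_i / sum(pop)``
    (random allocation, redrawn per trial); ``largest_remainder`` is the
    deterministic proportional rounding (Hamilton apportionment): floors of
    the exact shares, with the leftover units going to the largest
    fractional remainders (ties broken by lower cell index).

    Cells with zero population never receive patients. Returns an integer
    array summing to ``n_m``.
    """
    pops = np.asarray(mesh_populations, dtype=float)
    if n_m < 0:
        raise ValueError("n_m must be >= 0")
    if n_m == 0:
        return np.zeros(len(pops), dtype=int)
    total = pops.sum()
    if total <= 0:
        raise AllocationError(
            f"cannot allocate {n_m} patients: all mesh populations are zero")
    p = pops / total
    if mode == "multinomial":
        if rng is None:
            raise ValueError("multinomial mode requires an rng")
        return rng.multinomial(n_m, p)
    if mode == "largest_remainder":
        exact = n_m * p
        counts = np.floor(exact).astype(int)
        remainder = n_m - counts.sum()
        if remainder > 0:
            frac = exact - counts
            # stable sort: ties go to the lower index
            order = np.argsort(-frac, kind="stable")
            counts[order[:remainder]] += 1
        return counts
    raise ValueError(f"unknown allocation mode {mode!r}")


def sample_point_in_cell(cell: MeshCell, rng: np.random.Generator,
                         n: int = 1) -> np.ndarray:
    """Uniform draws inside the cell square; shape (n, 2).

    The square is the half-open box
    [cx - s/2, cx + s/2) x [cy - s/2, cy + s/2).
    """
    h = cell.size_m / 2.0
    xy = rng.random((n, 2)) * cell.size_m
    xy[:, 0] += cell.center_x - h
    xy[:, 1] += cell.center_y - h
    return xy


def _substream(seed: int, trial: int, municipality_id: str) -> np.random.Generator:
    # crc32 keys the municipality name into the seed sequence so streams are
    # independent per (trial, municipality) and stable under reordering
    key = zlib.crc32(municipality_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(trial), key]))


def generate_trial(region: StudyRegion, patient_counts: Mapping[str, int],
                   trial_index: int = 1, seed: int = 0,
                   mode: str = "multinomial") -> pd.DataFrame:
    """Generate one trial's hypothetical patient points.

    ``patient_counts`` maps municipality id to its patient count (the
    number of distinct home-care patients aged >=75 from the claims
    analysis, or any configured counts). Returns a DataFrame with columns
    ``id, trial, municipality_id, mesh_id, x, y`` and exactly
    ``sum(patient_counts.values())`` rows.
    """
    if mode not in ALLOCATION_MODES:
        raise ValueError(f"unknown allocation mode {mode!r}")
    cells_by_m = region.mesh_by_municipality()
    rows: list[tuple] = []
    for mid in sorted(patient_counts):
        n_m = int(patient_counts[mid])
        if n_m == 0:
            continue
        if mid not in region.municipalities:
            raise KeyError(f"unknown municipality {mid!r} in patient_counts")
        cells = cells_by_m.get(mid, [])
        pops = np.array([c.pop_75plus for c in cells], dtype=int)
        if pops.sum() == 0:
            raise AllocationError(
                f"municipality {mid!r}: {n_m} patients requested but no "
                "populated mesh cells")
        rng = _substream(seed, trial_index, mid)
        counts = allocate_to_meshes(n_m, pops, mode=mode, rng=rng)
        k = 0
        for cell, cnt in zip(cells, counts):
            if cnt == 0:
                continue
            xy = sample_point_in_cell(cell, rng, n=int(cnt))
            for j in range(int(cnt)):
                rows.append((f"{mid}-t{trial_index}-{k}", trial_index, mid,
                             cell.id, xy[j, 0], xy[j, 1]))
                k += 1
    df = pd.DataFrame(rows, columns=PATIENT_COLUMNS)
    return df
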