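"""Seed-deterministic synthetic tissue and cohort generators.

Two kinds of fixtures are produced:

* **Tissue point patterns** — tumor cells in disk-shaped "glands",
  stromal cells uniform in the complement, and immune cells either
  dispersed over the whole window or clustered inside a few circular
  foci. Two morphologies are provided: a stromal-predominant one (few
  small glands) and a mixed one (many large glands). Within a
  clustered/disperse pair the immune count is matched, so the two
  conditions differ only in immune placement — the setting in which
  single-number co-localization summaries fail to separate conditions
  that the six-parameter signature distinguishes.
* **Vector cohorts** — six-element archetype vectors plus Gaussian
  noise, with known planted labels, for exercising consensus clustering
  and subtype transfer.

All generators are pure functions of their spec (including the seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import CATEGORIES

#: morphology presets: gland layout within a 1000x1000 µm window
MORPHOLOGIES = {
    "stromal_predominant": dict(gland_count=8, gland_radius=60.0,
                                n_tumor=900, n_stroma=2700),
    "variable_mixed": dict(gland_count=20, gland_radius=80.0,
                           n_tumor=2100, n_stroma=1400),
}


@dataclass(frozen=True)
class TissueSpec:
    """Parameters of one simulated tissue sample."""

    window: tuple[float, float] = (1000.0, 1000.0)
    morphology: str = "stromal_predominant"
    n_tumor: int = 900
    n_stroma: int = 2700
    n_immune: int = 400
    immune_mode: str = "disperse"        # "disperse" | "clustered"
    cluster_radius: float = 50.0
    n_immune_foci: int = 2
    gland_count: int = 8
    gland_radius: float = 60.0
    seed: int = 0
    sample_id: str = "s0"

    @classmethod
    def preset(cls, morphology: str, immune_mode: str, seed: int, sample_id: str,
               n_immune: int = 400) -> "TissueSpec":
        if morphology not in MORPHOLOGIES:
            raise ValueError(f"unknown morphology {morphology!r}")
        p = MORPHOLOGIES[morphology]
        return cls(morphology=morphology, immune_mode=immune_mode, seed=seed,
                   sample_id=sample_id, n_immune=n_immune, **p)


@dataclass(frozen=True)
class CohortSpec:
    """Planted-archetype vector cohort."""

    archetypes: tuple
    n_per_archetype: int = 50
    noise_sd: float = 0.01
    seed: int = 0


def _disk_points(rng, centers, radius, n):
    """n points uniform in the union of equal disks (disk chosen uniformly)."""
    which = rng.integers(0, len(centers), size=n)
    u = rng.random(n)
    theta = rng.random(n) * 2.0 * math.pi
    rad = radius * np.sqrt(u)
    return centers[which] + np.column_stack([rad * np.cos(theta), rad * np.sin(theta)])


def _fit_centers(rng, n, radius, window):
    w, h = window
    if 2 * radius > w or 2 * radius > h:
        raise ValueError(f"disks of radius {radius} cannot fit the window {window}")
    return np.column_stack([
        rng.uniform(radius, w - radius, size=n),
        rng.uniform(radius, h - radius, size=n),
    ])


def simulate_tissue(spec: TissueSpec) -> pd.DataFrame:
    """Generate one tissue-like cell table (columns sample_id, x, y, compartment)."""
    if min(spec.n_tumor, spec.n_stroma, spec.n_immune) < 0:
        raise ValueError("cell counts must be non-negative")
    if spec.immune_mode not in ("disperse", "clustered"):
        raise ValueError(f"unknown immune_mode {spec.immune_mode!r}")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    w, h = spec.window
    glands = _fit_centers(rng, spec.gland_count, spec.gland_radius, spec.window)

    tumor = _disk_points(rng, glands, spec.gland_radius, spec.n_tumor)

    # stroma: uniform in the complement of the glands, by rejection
    stroma = np.empty((0, 2))
    while len(stroma) < spec.n_stroma:
        cand = np.column_stack([rng.uniform(0, w, 4 * spec.n_stroma or 1),
                                rng.uniform(0, h, 4 * spec.n_stroma or 1)])
        d2 = ((cand[:, None, :] - glands[None, :, :]) ** 2).sum(axis=2)
        keep = (d2 > spec.gland_radius**2).all(axis=1)
        stroma = np.vstack([stroma, cand[keep]])
    stroma = stroma[: spec.n_stroma]

    if spec.immune_mode == "disperse":
        immune = np.column_stack([rng.uniform(0, w, spec.n_immune),
                                  rng.uniform(0, h, spec.n_immune)])
    else:
        foci = _fit_centers(rng, spec.n_immune_foci, spec.cluster_radius, spec.window)
        immune = _disk_points(rng, foci, spec.cluster_radius, spec.n_immune)

    parts = [(tumor, "tumor"), (stroma, "stroma"), (immune, "immune")]
    frames = [
        pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1], "compartment": name})
        for pts, name in parts if len(pts)
    ]
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "sample_id", spec.sample_id)
    return out


def fig1_scenarios(seed: int = 0, n_immune: int = 400) -> dict[str, pd.DataFrame]:
    """The four showcase tissues: 2 morphologies x {clustered, disperse}.

    Immune counts are matched within each morphology pair; the two
    morphologies differ in tumor:stroma balance.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    out = {}
    for i, (morph, mode) in enumerate(
        [("stromal_predominant", "clustered"), ("stromal_predominant", "disperse"),
         ("variable_mixed", "clustered"), ("variable_mixed", "disperse")]
    ):
        name = f"{morph}_{mode}"
        spec = TissueSpec.preset(morph, mode, seed=int(ss[i].generate_state(1)[0] % 2**31),
                                 sample_id=name, n_immune=n_immune)
        out[name] = simulate_tissue(spec)
    return out


def replicate_pairs(n_pairs: int, seed: int, morphology: str = "stromal_predominant",
                    n_immune: int = 400) -> pd.DataFrame:
    """Seeded clustered/disperse replicate pairs at matched immune count.

    Returns one concatenated cell table; sample ids encode the pair index
    and condition (e.g. ``pair03_clustered``).
    """
    ss = np.random.SeedSequence(seed).spawn(2 * n_pairs)
    frames = []
    for p in range(n_pairs):
        for j, mode in enumerate(("clustered", "disperse")):
            spec = TissueSpec.preset(
                morphology, mode,
                seed=int(ss[2 * p + j].generate_state(1)[0] % 2**31),
                sample_id=f"pair{p:02d}_{mode}", n_immune=n_immune,
            )
            frames.append(simulate_tissue(spec))
    return pd.concat(frames, ignore_index=True)


def simulate_vector_cohort(spec: CohortSpec):
    """Archetype + Gaussian noise vector cohort with planted labels.

    Returns ``(matrix, labels)``: a samples x six DataFrame (values
    clipped to [0, 1]) and a Series of archetype indices.
    """
    arch = np.asarray(spec.archetypes, dtype=float)
    if arch.ndim != 2 or arch.shape[1] != 6:
        raise ValueError("archetypes must be a list of six-element vectors")
    if len(arch) < 2:
        raise ValueError("need at least two archetypes")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    rows, labels, ids = [], [], []
    for a_idx, a in enumerate(arch):
        noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_per_archetype, 6))
        rows.append(np.clip(a[None, :] + noise, 0.0, 1.0))
        labels.extend([a_idx] * spec.n_per_archetype)
        ids.extend(f"a{a_idx}_s{i}" for i in range(spec.n_per_archetype))
    m = pd.DataFrame(np.vstack(rows), columns=list(CATEGORIES),
                     index=pd.Index(ids, name="sample_id"))
    return m, pd.Series(labels, index=m.index, name="archetype")


# Planted archetypes: cyclic permutations of one base profile
# (tumor_only, it_low, it_high, stroma_only, is_low, is_high), so the three
# groups are geometrically exchangeable under the correlation metric — the
# clean-recovery setting where the planted k is unambiguous.
DEFAULT_ARCHETYPES = tuple(
    tuple(np.roll([0.5, 0.1, 0.05, 0.25, 0.05, 0.05], shift)) for shift in (0, 2, 4)
)


def simulate_csr_pair(intensity_t: float, intensity_i: float, window=(500.0, 500.0),
                      seed: int = 0, sample_id: str = "csr") -> pd.DataFrame:
    """Two independent homogeneous Poisson patterns labeled tumor/immune."""
    if intensity_t < 0 or intensity_i < 0:
        raise ValueError("intensities must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    w, h = window
    frames = []
    for name, lam in (("tumor", intensity_t), ("immune", intensity_i)):
        n = rng.poisson(lam * w * h)
        frames.append(pd.DataFrame({
            "x": rng.uniform(0, w, n), "y": rng.uniform(0, h, n), "compartment": name,
        }))
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "sample_id", sample_id)
    return out


def simulate_cohort(n_samples: int, seed: int = 0) -> pd.DataFrame:
    """A mixed synthetic cohort for end-to-end runs.

    Samples cycle through the four morphology/infiltrate scenarios so the
    cohort contains genuinely distinct spatial subtypes.
    """
    scenarios = [("stromal_predominant", "clustered"), ("stromal_predominant", "disperse"),
                 ("variable_mixed", "clustered"), ("variable_mixed", "disperse")]
    ss = np.random.SeedSequence(seed).spawn(n_samples)
    frames = []
    for i in range(n_samples):
        morph, mode = scenarios[i % len(scenarios)]
        spec = TissueSpec.preset(morph, mode,
                                 seed=int(ss[i].generate_state(1)[0] % 2**31),
                                 sample_id=f"sample{i:03d}")
        frames.append(simulate_tissue(spec))
    return pd.concat(frames, ignore_index=True)
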