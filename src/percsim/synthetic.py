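"""Synthetic study generator: ground truth, arrangements, behaviour, patterns.

Every downstream stage of the package is testable without any real data
because this module simulates the full study design end to end:

* a latent perceived-similarity structure per category, with a component
  shared by all observers and an observer-specific perturbation;
* circular-arena arrangements expressing each observer's own structure;
* category-exemplar 1-back behaviour whose errors and response times are
  coupled to the observer's own similarity structure;
* per-trial multivoxel patterns per region of interest, with region
  archetypes differing in which similarity components they encode.

Geometry. Latents live in an 8-dimensional space, but each category's four
exemplars lie in a category-specific 2D plane of that space and observer
perturbations act within the same plane. The arena (a 2D disc) can then
represent every observer's true within-category geometry exactly, which
makes the noiseless-recovery contract exact: as placement and pattern noise
go to zero, behaviour and brain RDMs converge to the true distance ranks.
Exemplar spacings are drawn at three characteristic scales so that the
high / medium / low similarity levels are non-degenerate.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import design
from .design import StudyConfig
from .rdm import make_rdm_frame


def rng_for(seed: int, *keys: int | str) -> np.random.Generator:
    """Deterministic child generator for a named stream.

    String keys are hashed with crc32 so streams are stable across runs and
    platforms; all entropy derives from the study seed.
    """
    ints = [seed & 0x7FFFFFFF]
    for k in keys:
        ints.append(zlib.crc32(k.encode()) if isinstance(k, str) else int(k))
    return np.random.default_rng(ints)


@dataclass(frozen=True)
class StructureParams:
    """Latent similarity-structure parameters.

    ``spacings`` are the three characteristic exemplar separations (arena
    ~latent units) that create fine / intermediate / coarse pair distances;
    ``sigma_observer`` scales the observer-specific in-plane perturbation of
    every exemplar and ``sigma_place`` the arena placement noise.
    """

    latent_dim: int = 8
    spacings: tuple[float, float, float] = (0.18, 0.75, 1.8)
    spacing_jitter: float = 0.2
    sigma_observer: float = 0.35
    sigma_place: float = 0.03

    def __post_init__(self) -> None:
        if self.latent_dim < 2:
            raise design.ConfigurationError("latent_dim must be >= 2")
        if self.sigma_observer < 0 or self.sigma_place < 0:
            raise design.ConfigurationError("sigma parameters must be >= 0")


@dataclass(frozen=True)
class RegionSpec:
    """Archetype of a simulated region of interest.

    Weights set how strongly trial patterns encode the shared latent
    structure, the observer's own (shared + perturbation) structure, and the
    intermediate model-feature vector; ``sigma_noise`` is per-trial,
    per-voxel Gaussian noise.
    """

    name: str
    n_voxels: int = 60
    w_shared: float = 0.0
    w_observer: float = 0.0
    w_intermediate: float = 0.0
    sigma_noise: float = 1.0
    pure_noise_ok: bool = False

    def __post_init__(self) -> None:
        if self.n_voxels < 2:
            raise design.ConfigurationError("regions need at least 2 voxels")
        if min(self.w_shared, self.w_observer, self.w_intermediate) < 0:
            raise design.ConfigurationError("region weights must be >= 0")
        if (
            self.w_shared == self.w_observer == self.w_intermediate == 0
            and not self.pure_noise_ok
        ):
            raise design.ConfigurationError(
                f"region {self.name!r} has no signal; set pure_noise_ok=True "
                "for an intentional noise-only control"
            )


def default_regions() -> list[RegionSpec]:
    """The three region archetypes used throughout the package's analyses.

    * ``noise`` — no stimulus information at all (negative control);
    * ``LOC-like`` — encodes only the structure shared across observers
      (plus intermediate features), with noise high enough that only coarse
      exemplar differences survive;
    * ``PrC-like`` — encodes the observer's own structure with high
      fidelity, so even fine-grained, observer-specific distinctions are
      represented.
    """
    return [
        RegionSpec("noise", sigma_noise=1.0, pure_noise_ok=True),
        RegionSpec(
            "LOC-like",
            w_shared=1.0,
            w_intermediate=0.5,
            sigma_noise=6.0,
        ),
        RegionSpec(
            "PrC-like",
            w_shared=0.2,
            w_observer=1.0,
            sigma_noise=1.0,
        ),
    ]


@dataclass(frozen=True)
class PerfParams:
    """Behavioural coupling parameters for the simulated 1-back task.

    Error probability on same-category catch trials follows a logistic in
    the observer's own perceived similarity of the trial pair; response time
    on correct same-category trials rises linearly with that similarity.
    """

    base_error: float = 0.08
    error_slope: float = 3.0
    base_rt: float = 0.7
    rt_slope: float = 0.35
    rt_noise: float = 0.15
    miss_rate: float = 0.02
    exemplar_catch_error: float = 0.03
    false_alarm: float = 0.02


@dataclass(frozen=True)
class StudyGroundTruth:
    """Latent structure of one simulated study."""

    config: StudyConfig
    params: StructureParams
    centres: np.ndarray  # (C, D) category centres in latent space
    planes: np.ndarray  # (C, D, 2) orthonormal in-plane bases
    plane_coords: np.ndarray  # (C, E, 2) shared exemplar coordinates
    offsets: np.ndarray  # (O, C, E, 2) observer perturbations, in-plane
    intermediate: np.ndarray  # (C, E, D) intermediate feature vectors

    def latent(self, category: int, exemplar: int) -> np.ndarray:
        """Shared latent vector of exemplar (1-based ids)."""
        c, e = category - 1, exemplar - 1
        return self.centres[c] + self.planes[c] @ self.plane_coords[c, e]

    def observer_plane_coords(self, observer: int) -> np.ndarray:
        """(C, E, 2) in-plane coordinates of one observer's true structure."""
        return self.plane_coords + self.offsets[observer - 1]

    def observer_latent(
        self, observer: int, category: int, exemplar: int
    ) -> np.ndarray:
        c, e = category - 1, exemplar - 1
        coords = self.plane_coords[c, e] + self.offsets[observer - 1, c, e]
        return self.centres[c] + self.planes[c] @ coords

    def true_distance_rdm(self, observer: int) -> pd.DataFrame:
        """Long-form RDM of the observer's true within-category distances."""
        coords = self.observer_plane_coords(observer)
        rows = []
        for c in range(self.config.n_categories):
            for i, j in design.exemplar_pairs(self.config.n_exemplars_per_category):
                d = float(np.linalg.norm(coords[c, i - 1] - coords[c, j - 1]))
                rows.append((c + 1, i, j, d))
        frame = pd.DataFrame(
            rows, columns=["category", "exemplar_i", "exemplar_j", "raw"]
        )
        rdm = make_rdm_frame(frame)
        rdm.insert(0, "observer", observer)
        return rdm


def make_ground_truth(
    config: StudyConfig, params: StructureParams | None = None
) -> StudyGroundTruth:
    """Draw the latent similarity structure of a study, reproducibly.

    Exemplar 1 anchors each category; exemplars 2-4 sit at the three
    characteristic spacings (with lognormal jitter) in random in-plane
    directions, which yields six pair distances spanning fine to coarse.
    """
    params = params or StructureParams()
    cfg = config
    C, E, D = cfg.n_categories, cfg.n_exemplars_per_category, params.latent_dim
    rng = rng_for(cfg.seed, "ground-truth")

    centres = rng.normal(0.0, 1.0, size=(C, D))
    # constant centre norm: keeps pattern-correlation denominators comparable
    # across categories, so brain dissimilarity ranks track distance ranks
    centres *= np.sqrt(D) / np.linalg.norm(centres, axis=1, keepdims=True)
    planes = np.empty((C, D, 2))
    for c in range(C):
        q, _ = np.linalg.qr(rng.normal(size=(D, 2)))
        planes[c] = q

    spacings = np.asarray(params.spacings)
    plane_coords = np.zeros((C, E, 2))
    for c in range(C):
        for e in range(1, E):
            scale = spacings[(e - 1) % len(spacings)] * np.exp(
                rng.normal(0.0, params.spacing_jitter)
            )
            theta = rng.uniform(0, 2 * np.pi)
            plane_coords[c, e] = scale * np.array([np.cos(theta), np.sin(theta)])
        plane_coords[c] -= plane_coords[c].mean(axis=0)

    offsets = rng.normal(
        0.0, params.sigma_observer, size=(cfg.n_observers, C, E, 2)
    )

    mix = rng.normal(0.0, 1.0 / np.sqrt(D), size=(D, D))
    intermediate = np.empty((C, E, D))
    for c in range(C):
        for e in range(E):
            latent = centres[c] + planes[c] @ plane_coords[c, e]
            intermediate[c, e] = np.tanh(mix @ latent)

    return StudyGroundTruth(
        config=cfg,
        params=params,
        centres=centres,
        planes=planes,
        plane_coords=plane_coords,
        offsets=offsets,
        intermediate=intermediate,
    )


def _classical_mds_2d(dist: np.ndarray) -> np.ndarray:
    """Classical (Torgerson) scaling of a distance matrix to 2D."""
    n = dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:2]
    w2 = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(w2)


def simulate_arrangements(
    gt: StudyGroundTruth, observer: int, fill: float = 0.95
) -> pd.DataFrame:
    """One observer's arena arrangements, one per category.

    The observer's true 4-point distances are embedded to 2D by classical
    scaling, rescaled to fill the unit-radius arena, and perturbed by
    placement noise. If noise pushes a point outside the arena, the whole
    arrangement is shrunk uniformly (a monotone transform, so percentile
    RDMs are unaffected).
    """
    if not 1 <= observer <= gt.config.n_observers:
        raise design.ConfigurationError(f"observer {observer} out of range")
    rng = rng_for(gt.config.seed, "arrangement", observer)
    coords = gt.observer_plane_coords(observer)
    embeddings = []
    for c in range(gt.config.n_categories):
        pts = coords[c]
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        emb = _classical_mds_2d(dist)
        emb -= emb.mean(axis=0)
        embeddings.append(emb)
    # one spatial scale across all of the observer's arenas, so pooled
    # percentiles over categories remain faithful to the true distance ranks
    global_r = max(np.linalg.norm(e, axis=1).max() for e in embeddings)
    scale = fill / global_r if global_r > 0 else 1.0
    rows = []
    for c, emb in enumerate(embeddings):
        emb = emb * scale
        emb = emb + rng.normal(0.0, gt.params.sigma_place, size=emb.shape)
        out_r = np.linalg.norm(emb, axis=1).max()
        if out_r > 1.0:
            emb /= out_r
        for e in range(gt.config.n_exemplars_per_category):
            rows.append((observer, c + 1, e + 1, emb[e, 0], emb[e, 1]))
    return pd.DataFrame(rows, columns=["observer", "category", "exemplar", "x", "y"])


def _own_similarity(gt: StudyGroundTruth, observer: int) -> dict[tuple, float]:
    """Similarity (1 - dissimilarity percentile) of each within-category pair
    under the observer's own true structure."""
    rdm = gt.true_distance_rdm(observer)
    return {
        (r.category, r.exemplar_i, r.exemplar_j): 1.0 - r.percentile
        for r in rdm.itertuples()
    }


def simulate_behaviour(
    gt: StudyGroundTruth,
    observer: int,
    trials: pd.DataFrame,
    params: PerfParams | None = None,
) -> pd.DataFrame:
    """Simulate one observer's 1-back responses for a trial sequence.

    Returns a frame aligned with ``trials`` (run, position) carrying the
    response ("none", "same_exemplar_key", "same_category_key") and the RT
    in seconds for emitted responses (NaN otherwise).
    """
    params = params or PerfParams()
    rng = rng_for(gt.config.seed, "behaviour", observer)
    sim = _own_similarity(gt, observer)
    base_logit = logit(np.clip(params.base_error, 1e-6, 1 - 1e-6))

    responses: list[str] = []
    rts: list[float] = []
    prev_exemplar: tuple[int, int] | None = None
    prev_run = None
    for t in trials.sort_values(["run", "position"]).itertuples():
        if t.run != prev_run:
            prev_exemplar = None
            prev_run = t.run
        response, rt = "none", np.nan

        def emit(key: str, mean_rt: float) -> tuple[str, float]:
            return key, max(0.15, mean_rt + rng.normal(0.0, params.rt_noise))

        if t.trial_type == design.SAME_EXEMPLAR_CATCH:
            if rng.random() >= params.miss_rate:
                if rng.random() < params.exemplar_catch_error:
                    response, rt = emit("same_category_key", params.base_rt)
                else:
                    response, rt = emit("same_exemplar_key", params.base_rt)
        elif t.trial_type == design.SAME_CATEGORY_CATCH:
            if prev_exemplar is None:
                raise design.GenerationError(
                    f"run {t.run} position {t.position}: catch trial without "
                    "a predecessor"
                )
            i, j = sorted((prev_exemplar[1], t.exemplar))
            s = sim[(t.category, i, j)]
            if rng.random() >= params.miss_rate:
                p_err = expit(base_logit + params.error_slope * (s - 0.5))
                if rng.random() < p_err:
                    response, rt = emit(
                        "same_exemplar_key", params.base_rt + params.rt_slope * s
                    )
                else:
                    response, rt = emit(
                        "same_category_key", params.base_rt + params.rt_slope * s
                    )
        else:  # no-response trial
            if rng.random() < params.false_alarm:
                key = (
                    "same_exemplar_key"
                    if rng.random() < 0.5
                    else "same_category_key"
                )
                response, rt = emit(key, params.base_rt)
        responses.append(response)
        rts.append(rt)
        prev_exemplar = (t.category, t.exemplar)

    out = trials.sort_values(["run", "position"]).reset_index(drop=True).copy()
    out["observer"] = observer
    out["response"] = responses
    out["rt"] = rts
    return out


@dataclass
class NeuralPatternSet:
    """Per-trial voxel patterns of one observer in one region."""

    observer: int
    region: str
    trials: pd.DataFrame  # (run, position, category, exemplar, trial_type)
    data: np.ndarray  # (n_trials, n_voxels), row-aligned with trials

    def __post_init__(self) -> None:
        if len(self.trials) != self.data.shape[0]:
            raise design.ConfigurationError(
                "pattern rows and trial index differ in length"
            )

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


def simulate_voxel_patterns(
    gt: StudyGroundTruth,
    observer: int,
    region: RegionSpec,
    trials: pd.DataFrame,
) -> NeuralPatternSet:
    """Simulate per-trial voxel patterns for one observer x region.

    Each trial's pattern is a fixed random linear read-out of the trial
    exemplar's signal vector (shared latent, observer's own latent, and
    intermediate features, weighted per the region archetype) plus i.i.d.
    Gaussian noise. The read-out is fixed across runs, so patterns are
    stable up to noise.
    """
    cfg = gt.config
    D = gt.params.latent_dim
    rng_readout = rng_for(cfg.seed, "readout", observer, region.name)
    readout = rng_readout.normal(0.0, 1.0 / np.sqrt(D), size=(region.n_voxels, D))

    signals = np.zeros(
        (cfg.n_categories, cfg.n_exemplars_per_category, region.n_voxels)
    )
    for c in range(1, cfg.n_categories + 1):
        for e in range(1, cfg.n_exemplars_per_category + 1):
            vec = (
                region.w_shared * gt.latent(c, e)
                + region.w_observer * gt.observer_latent(observer, c, e)
                + region.w_intermediate * gt.intermediate[c - 1, e - 1]
            )
            signals[c - 1, e - 1] = readout @ vec

    trials = trials.sort_values(["run", "position"]).reset_index(drop=True)
    rng_noise = rng_for(cfg.seed, "noise", observer, region.name)
    noise = rng_noise.normal(
        0.0, region.sigma_noise, size=(len(trials), region.n_voxels)
    )
    data = (
        signals[trials["category"].to_numpy() - 1, trials["exemplar"].to_numpy() - 1]
        + noise
    )
    return NeuralPatternSet(
        observer=observer, region=region.name, trials=trials, data=data
    )


@dataclass
class StudyData:
    """Everything one simulated study produces."""

    config: StudyConfig
    ground_truth: StudyGroundTruth
    regions: list[RegionSpec]
    arrangements: pd.DataFrame  # all observers stacked
    trials: dict[int, pd.DataFrame]  # per observer
    behaviour: dict[int, pd.DataFrame]  # per observer
    patterns: dict[tuple[int, str], NeuralPatternSet] = field(default_factory=dict)

    @property
    def observers(self) -> list[int]:
        return list(range(1, self.config.n_observers + 1))


def simulate_study(
    config: StudyConfig | None = None,
    regions: list[RegionSpec] | None = None,
    structure: StructureParams | None = None,
    perf: PerfParams | None = None,
    with_patterns: bool = True,
) -> StudyData:
    """Simulate a complete study under one configuration and seed."""
    cfg = config or StudyConfig()
    regions = default_regions() if regions is None else regions
    gt = make_ground_truth(cfg, structure)
    arrangements, trials, behaviour, patterns = [], {}, {}, {}
    for o in range(1, cfg.n_observers + 1):
        arrangements.append(simulate_arrangements(gt, o))
        seq_seed = int(rng_for(cfg.seed, "trials", o).integers(2**31 - 1))
        trials[o] = design.generate_trial_sequence(cfg, seed=seq_seed)
        behaviour[o] = simulate_behaviour(gt, o, trials[o], perf)
        if with_patterns:
            for region in regions:
                patterns[(o, region.name)] = simulate_voxel_patterns(
                    gt, o, region, trials[o]
                )
    return StudyData(
        config=cfg,
        ground_truth=gt,
        regions=regions,
        arrangements=pd.concat(arrangements, ignore_index=True),
        trials=trials,
        behaviour=behaviour,
        patterns=patterns,
    )


def render_stimuli(
    gt: StudyGroundTruth, size: int = 64
) -> dict[tuple[int, int], np.ndarray]:
    """Procedural grayscale stimulus images, one per exemplar.

    Each category gets a seeded base texture (a superposition of oriented
    gratings); each exemplar modulates the texture with Gaussian blobs whose
    placement follows the exemplar's shared in-plane coordinates, so image
    similarity tracks the shared latent structure. Intended for exercising
    the HMAX front end, not as realistic object photographs.
    """
    cfg = gt.config
    ys, xs = np.mgrid[-1 : 1 : size * 1j, -1 : 1 : size * 1j]
    images = {}
    for c in range(1, cfg.n_categories + 1):
        rng = rng_for(cfg.seed, "stimuli", c)
        base = np.zeros((size, size))
        for _ in range(3):
            theta = rng.uniform(0, np.pi)
            freq = rng.uniform(2.0, 6.0)
            phase = rng.uniform(0, 2 * np.pi)
            base += rng.uniform(0.3, 1.0) * np.cos(
                2 * np.pi * freq * (np.cos(theta) * xs + np.sin(theta) * ys) + phase
            )
        for e in range(1, cfg.n_exemplars_per_category + 1):
            cx, cy = np.clip(0.35 * gt.plane_coords[c - 1, e - 1], -0.8, 0.8)
            blob = np.exp(-(((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * 0.12**2)))
            img = 0.5 * base / max(np.abs(base).max(), 1e-9) + blob
            img -= img.min()
            img /= max(img.max(), 1e-9)
            images[(c, e)] = img
    return images
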