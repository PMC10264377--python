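"""Seeded synthetic cohorts of slides with known latent tile labels.

The generator emulates the structure of a pancreatic-adenocarcinoma
whole-slide cohort *after* featurization: each slide is a bag of per-tile
feature vectors, each tile carries a latent label (neoplastic or not; tumor
vs stroma; for tumor tiles a continuous phenotype on the classical(0) ↔
basal-like(1) axis; for stroma tiles an active/inactive state), and each
patient carries bulk-like labels derived from their tiles plus a survival
time whose hazard increases with the basal fraction.

Patients belong to one of four archetypes of intratumor heterogeneity:

* ``main_classical`` — tumor tiles concentrated near phenotype 0
* ``main_basal``     — concentrated near 1
* ``hybrid``         — bimodal, clearly classical *and* clearly basal tiles
* ``intermediary``   — concentrated near 0.5, never clearly either

Features are class-conditional isotropic Gaussians: four fixed random
orthonormal directions per run carry the neoplastic, cell-type, phenotype and
stroma-state signals, and the tumor-tile mean interpolates linearly between
the classical and basal endpoints, whose distance is ``class_sep * noise_sd``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .containers import ComponentScores, PatientRecord, SlideBag
from .exceptions import ConfigurationError, UndefinedLabelError

ARCHETYPES = ("main_classical", "main_basal", "hybrid", "intermediary")

#: archetype mix observed in a large resected-PDAC cohort
#: (192, 84, 45, 130 of 451 patients)
DEFAULT_ARCHETYPE_PROPS = (192 / 451, 84 / 451, 45 / 451, 130 / 451)

#: per-archetype distribution of the basal fraction of tumor tiles;
#: ("beta", a, b) or ("uniform", lo, hi)
#: clear archetypes carry at most 0.5% opposite-pole tumor tiles so the 99th
#: percentile reflects the dominant contingent even at desk-scale bag sizes
DEFAULT_BASAL_FRAC_DISTS: Dict[str, Tuple] = {
    "main_classical": ("uniform", 0.0, 0.005),
    "main_basal": ("uniform", 0.995, 1.0),
    "hybrid": ("uniform", 0.35, 0.65),
    "intermediary": ("uniform", 0.45, 0.55),
}


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic-cohort generator.

    ``class_sep`` is the mean shift between latent classes in units of
    ``noise_sd``; 0 removes all feature signal.  ``survival_beta`` is the
    log-hazard coefficient on the patient's basal fraction, ``base_scale``
    the event-time scale (months) at basal fraction 0.
    """

    n_patients: int = 100
    archetype_props: Tuple[float, float, float, float] = DEFAULT_ARCHETYPE_PROPS
    slides_per_patient: Union[int, Tuple[int, int]] = 1
    tiles_per_slide: Tuple[int, int] = (120, 240)
    feature_dim: int = 64
    class_sep: float = 3.0
    noise_sd: float = 1.0
    basal_frac_dists: Dict[str, Tuple] = field(
        default_factory=lambda: dict(DEFAULT_BASAL_FRAC_DISTS))
    nonneoplastic_frac: float = 0.2
    stroma_frac: float = 0.4
    #: per-patient probability that a stroma tile is "active" is drawn from
    #: this Beta, so stroma activation genuinely varies across patients
    active_stroma_dist: Tuple[float, float] = (2.0, 2.0)
    label_noise_sd: float = 0.05
    label_flip_rate: float = 0.0
    survival_beta: float = 1.2
    base_scale: float = 40.0
    censor_rate: float = 0.3
    allocation: str = "exact"          # "exact" | "multinomial"
    seed: int = 0

    def __post_init__(self):
        props = np.asarray(self.archetype_props, dtype=float)
        if props.shape != (4,) or np.any(props < 0) or np.any(props > 1):
            raise ConfigurationError("archetype_props must be 4 values in [0,1]")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"archetype_props must sum to 1 (got {props.sum()!r})")
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        n_requested = int(np.sum(props > 0))
        if self.allocation == "exact" and self.n_patients < n_requested:
            raise ConfigurationError(
                f"exact allocation of {n_requested} archetypes requires "
                f"n_patients >= {n_requested}")
        if self.allocation not in ("exact", "multinomial"):
            raise ConfigurationError(f"unknown allocation {self.allocation!r}")
        if self.feature_dim < 2:
            raise ConfigurationError("feature_dim must be >= 2")
        lo, hi = self.tiles_per_slide
        if lo < 1 or hi < lo:
            raise ConfigurationError("tiles_per_slide must be a range with lo >= 1")
        if self.class_sep < 0:
            raise ConfigurationError("class_sep must be non-negative")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        for name, frac in (("nonneoplastic_frac", self.nonneoplastic_frac),
                           ("censor_rate", self.censor_rate)):
            if not 0 <= frac < 1:
                raise ConfigurationError(f"{name} must be in [0,1)")
        if not 0 < self.stroma_frac < 1:
            raise ConfigurationError("stroma_frac must be in (0,1)")

    def slides_range(self) -> Tuple[int, int]:
        s = self.slides_per_patient
        return (s, s) if isinstance(s, int) else tuple(s)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["basal_frac_dists"] = {k: list(v) for k, v in d["basal_frac_dists"].items()}
        return d


@dataclass
class Cohort:
    """A generated cohort: slide bags, patient records, latent tile labels."""

    slides: List[SlideBag]
    patients: List[PatientRecord]
    tiles: pd.DataFrame            # one row per tile, latent ground truth
    config: SyntheticConfig
    directions: np.ndarray         # (feature_dim, 4) orthonormal signal axes

    def slides_of(self, patient_id: str) -> List[SlideBag]:
        return [s for s in self.slides if s.patient_id == patient_id]


def allocate_archetypes(props, n: int, rng: np.random.Generator,
                        method: str = "exact") -> np.ndarray:
    """Archetype index per patient.

    ``exact`` uses largest-remainder apportionment so counts match the
    proportions as closely as integers allow (and exactly when n*props are
    integers); ``multinomial`` draws counts at random.
    """
    props = np.asarray(props, dtype=float)
    if method == "multinomial":
        counts = rng.multinomial(n, props)
    else:
        raw = props * n
        counts = np.floor(raw).astype(int)
        rem = raw - counts
        for i in np.argsort(-rem)[: n - counts.sum()]:
            counts[i] += 1
    out = np.repeat(np.arange(4), counts)
    rng.shuffle(out)
    return out


def _draw_basal_fraction(dist: Tuple, rng: np.random.Generator) -> float:
    kind = dist[0]
    if kind == "beta":
        return float(rng.beta(dist[1], dist[2]))
    if kind == "uniform":
        return float(rng.uniform(dist[1], dist[2]))
    raise ConfigurationError(f"unknown basal-fraction distribution {kind!r}")


def _draw_phenotypes(archetype: str, f: float, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Tumor-tile phenotypes for one slide.

    Clearly differentiated archetypes draw each tile near 0 or near 1
    (Bernoulli(f) mixture of sharp Betas); intermediary tumors draw every
    tile near 0.5 and never reach either pole.
    """
    if archetype == "intermediary":
        return rng.beta(25.0, 25.0, size=n)
    is_basal = rng.random(n) < f
    phen = rng.beta(1.5, 14.0, size=n)          # classical pole, mean ~0.10
    phen[is_basal] = rng.beta(14.0, 1.5, size=int(is_basal.sum()))
    return phen


def derive_bulk_labels(tiles: pd.DataFrame,
                       noise_sd_label: float = 0.0,
                       rng: Optional[np.random.Generator] = None,
                       flip_rate: float = 0.0,
                       ) -> Tuple[str, ComponentScores]:
    """Bulk-like labels of one patient from their neoplastic tiles.

    The basal component is the mean tumor-tile phenotype plus Gaussian noise;
    classical is the mean of (1 - phenotype); the stroma components are the
    active/inactive stroma-tile fractions among neoplastic tiles.  The binary
    class compares the *noiseless* basal and classical components; ties break
    to classical.  ``flip_rate`` optionally mislabels the class at random.
    """
    tumor = tiles[tiles["cell_type"] == "tumor"]
    if len(tumor) == 0:
        raise UndefinedLabelError("patient has no tumor tiles; labels undefined")
    if rng is None:
        rng = np.random.default_rng()
    phen = tumor["phenotype"].to_numpy(dtype=float)
    neo = tiles[tiles["neoplastic"] == 1]
    basal0 = float(phen.mean())
    classical0 = float((1.0 - phen).mean())
    stroma = neo[neo["cell_type"] == "stroma"]
    active0 = float((stroma["stroma_state"] == "active").sum() / len(neo))
    inactive0 = float((stroma["stroma_state"] == "inactive").sum() / len(neo))
    noise = rng.normal(0.0, noise_sd_label, size=4) if noise_sd_label > 0 else np.zeros(4)
    comps = ComponentScores(classical=classical0 + noise[0],
                            basal=basal0 + noise[1],
                            stroma_active=active0 + noise[2],
                            stroma_inactive=inactive0 + noise[3])
    purist = "basal" if basal0 > classical0 else "classical"
    if flip_rate > 0 and rng.random() < flip_rate:
        purist = "classical" if purist == "basal" else "basal"
    return purist, comps


def generate_survival(basal_fraction: float, beta: float, base_scale: float,
                      censor_rate: float,
                      rng: Union[int, np.random.Generator],
                      ) -> Tuple[float, int]:
    """One (time, event) draw with hazard ``exp(beta * basal_fraction)``.

    Event times are exponential with scale ``base_scale *
    exp(-beta * basal_fraction)``.  Censoring is an independent exponential
    whose rate is set so each subject is censored with probability
    ``censor_rate``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if base_scale <= 0:
        raise ConfigurationError("base_scale must be positive")
    rate = np.exp(beta * basal_fraction) / base_scale
    t = rng.exponential(1.0 / rate)
    if censor_rate <= 0:
        return float(t), 1
    rate_c = rate * censor_rate / (1.0 - censor_rate)
    c = rng.exponential(1.0 / rate_c)
    return (float(t), 1) if t <= c else (float(c), 0)


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a full cohort; deterministic for a fixed config (incl. seed)."""
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_feat, rng_label, rng_surv = (
        np.random.default_rng(s) for s in ss.spawn(4))

    d = config.feature_dim
    # orthonormal signal axes: neoplastic, cell-type, phenotype, stroma-state
    q, _ = np.linalg.qr(rng_feat.normal(size=(d, 4)))
    directions = q[:, :4]
    u_neo, u_cell, u_phen, u_str = directions.T
    amp = config.class_sep * config.noise_sd

    archetype_idx = allocate_archetypes(
        config.archetype_props, config.n_patients, rng_struct, config.allocation)

    slides: List[SlideBag] = []
    patients: List[PatientRecord] = []
    tile_rows = []
    s_lo, s_hi = config.slides_range()
    t_lo, t_hi = config.tiles_per_slide

    for p in range(config.n_patients):
        pid = f"P{p:04d}"
        archetype = ARCHETYPES[archetype_idx[p]]
        f = _draw_basal_fraction(config.basal_frac_dists[archetype], rng_struct)
        p_active = float(rng_struct.beta(*config.active_stroma_dist))
        n_slides = int(rng_struct.integers(s_lo, s_hi + 1))
        patient_tiles = []
        slide_ids = []

        for s in range(n_slides):
            sid = f"{pid}_S{s}"
            n_tiles = int(rng_struct.integers(t_lo, t_hi + 1))
            neoplastic = (rng_struct.random(n_tiles)
                          >= config.nonneoplastic_frac).astype(int)
            cell_type = np.where(neoplastic == 0, "none",
                                 np.where(rng_struct.random(n_tiles)
                                          < config.stroma_frac,
                                          "stroma", "tumor"))
            cell_type[neoplastic == 0] = "none"
            phenotype = np.full(n_tiles, np.nan)
            tumor_mask = cell_type == "tumor"
            phenotype[tumor_mask] = _draw_phenotypes(
                archetype, f, int(tumor_mask.sum()), rng_struct)
            stroma_state = np.full(n_tiles, "none", dtype=object)
            stroma_mask = cell_type == "stroma"
            stroma_state[stroma_mask] = np.where(
                rng_struct.random(int(stroma_mask.sum())) < p_active,
                "active", "inactive")

            means = np.zeros((n_tiles, d))
            means[neoplastic == 1] += amp * u_neo
            means[tumor_mask] += amp * u_cell
            # classical endpoint at -amp/2, basal at +amp/2 along u_phen
            means[tumor_mask] += np.outer(
                phenotype[tumor_mask] - 0.5, amp * u_phen)
            means[stroma_state == "active"] += 0.5 * amp * u_str
            means[stroma_state == "inactive"] -= 0.5 * amp * u_str
            feats = means + config.noise_sd * rng_feat.normal(size=(n_tiles, d))

            ncols = max(1, int(np.ceil(np.sqrt(n_tiles))))
            idx = np.arange(n_tiles)
            slides.append(SlideBag(slide_id=sid, patient_id=pid,
                                   features=feats, tile_index=idx,
                                   rows=idx // ncols, cols=idx % ncols))
            slide_ids.append(sid)
            patient_tiles.append(pd.DataFrame({
                "patient_id": pid, "slide_id": sid, "tile_index": idx,
                "row": idx // ncols, "col": idx % ncols,
                "neoplastic": neoplastic, "cell_type": cell_type,
                "phenotype": phenotype, "stroma_state": stroma_state,
            }))

        ptiles = pd.concat(patient_tiles, ignore_index=True)
        tile_rows.append(ptiles)
        purist, comps = derive_bulk_labels(
            ptiles, config.label_noise_sd, rng_label, config.label_flip_rate)
        phen = ptiles.loc[ptiles["cell_type"] == "tumor", "phenotype"]
        basal_fraction = float(phen.mean())
        time, event = generate_survival(
            basal_fraction, config.survival_beta, config.base_scale,
            config.censor_rate, rng_surv)
        patients.append(PatientRecord(
            patient_id=pid, purist_class=purist, components=comps,
            time=time, event=event, slide_ids=slide_ids,
            archetype=archetype, basal_fraction=basal_fraction))

    tiles = pd.concat(tile_rows, ignore_index=True)
    return Cohort(slides=slides, patients=patients, tiles=tiles,
                  config=config, directions=directions)
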