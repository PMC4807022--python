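"""Synthetic seed populations with the statistical structure the pipeline
assumes, so every stage is testable without any external data.

Sizes are drawn per seed from a trivariate lognormal (length, width,
thickness) with species-specific means and coefficients of variation and a
tunable log-scale correlation structure: "wild" species have strongly
coupled length/width/thickness (the allometric pattern of undomesticated
seeds), while cultivated seeds have length decoupled from width and
thickness.  A shared accession random effect splits each species' total
variance into a between-accession and a within-accession part; the
within-accession part is kept small (cv ~ 0.07), which is what makes
per-accession means stabilize near 20 seeds.

Shape is generated in normalized elliptic-Fourier coefficient space: each
seed's harmonics 2..9 (both views) are a species signature plus a low-rank
combination of shared deformation modes (species score + accession offset +
seed noise) plus a small independent coefficient floor.  The low-rank
structure matters: independent per-coefficient noise in 64 dimensions would
be linearly separable at unrealistic rates.  Each seed's outline is then
reconstructed at the drawn physical size and pushed through the genuine
forward transform and normalization, so records carry coefficients produced
by the same code path as real silhouettes, and the dorsal surface is the
actual polygon area of the generated outline (preserving the
length-surface correlation).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import COEFF_COLUMNS, Dataset, load_bundled_metadata
from .eft_core import EFTCoefficients, eft_forward, eft_inverse, normalize, retained_vector
from .outline_ops import polygon_area

__all__ = ["SpeciesTemplate", "generate_population", "paper_like_panel", "phoenix_templates"]

_HARMONICS = np.arange(2, 10)
#: per-coefficient amplitude decay with harmonic rank (smooth outlines)
_DECAY = np.repeat((2.0 / _HARMONICS) ** 1.5, 4)
_MODE_SCALES = np.array([0.030, 0.022, 0.016, 0.012, 0.009, 0.007])
_N_MODES = len(_MODE_SCALES)


def _mode_matrix(rng_seed: int) -> np.ndarray:
    """Fixed 32 x 6 deformation-mode basis with decaying loadings.  The A2
    row is damped: the egg asymmetry is a conserved trait, and keeping the
    population's A2 well away from zero keeps the canonical starting-point
    sign stable across seeds."""
    rng = np.random.default_rng(rng_seed)
    m = rng.normal(size=(32, _N_MODES)) * _DECAY[:, None] * _MODE_SCALES[None, :]
    m[0, :] *= 0.3  # A2
    return m


_MODES_DORSAL = _mode_matrix(771001)
_MODES_LATERAL = _mode_matrix(771002)


def _base_vector(rng_seed: int, egg: float) -> np.ndarray:
    rng = np.random.default_rng(rng_seed)
    v = rng.normal(size=32) * 0.008 * _DECAY
    v[0] += egg  # A2: pointed seed base
    return v


_BASE_DORSAL = _base_vector(771003, 0.07)
_BASE_LATERAL = _base_vector(771004, 0.06)

# log-scale size correlations (length-width, length-thickness, width-thickness)
_CORR_WILD = np.array([[1.0, 0.85, 0.82], [0.85, 1.0, 0.93], [0.82, 0.93, 1.0]])
_CORR_CULT = np.array([[1.0, 0.15, 0.10], [0.15, 1.0, 0.93], [0.10, 0.93, 1.0]])


@dataclass
class SpeciesTemplate:
    """Generative parameters for one species (or status group).

    ``size_means``/``size_cv`` are (length, width, thickness) in cm and
    total coefficients of variation; ``size_correlation`` is the log-scale
    correlation matrix (its (0,1) entry is the width-length target);
    ``accession_effect_sd`` is the between-accession share of the total sd.
    ``mode_scores`` places the species in the shared shape-mode space;
    ``shape_noise_sd`` is the independent per-coefficient floor.
    """

    name: str
    status: str = "wild_reference"
    n_accessions: int = 3
    seeds_per_accession: int = 20
    size_means: tuple = (1.2, 0.7, 0.6)
    size_cv: tuple = (0.12, 0.09, 0.09)
    size_correlation: np.ndarray = field(default_factory=lambda: _CORR_WILD.copy())
    elongation: float = 1.7
    egg_asymmetry: float = 0.0
    shape_noise_sd: float = 0.006
    accession_effect_sd: float = 0.6
    mode_scores: np.ndarray = field(default_factory=lambda: np.zeros(_N_MODES))
    mode_within_sd: float = 1.0
    mode_accession_sd: float = 0.35
    role: str = "wild"
    accessions: list | None = None  # optional [(sample_id, n_seeds), ...]

    def __post_init__(self) -> None:
        self.size_means = tuple(float(v) for v in self.size_means)
        self.size_cv = tuple(float(v) for v in self.size_cv)
        self.mode_scores = np.asarray(self.mode_scores, dtype=float)
        if any(v <= 0 for v in self.size_means) or any(v <= 0 for v in self.size_cv):
            raise ValueError("size means and cvs must be positive")
        if not (0.0 <= self.accession_effect_sd < 1.0):
            raise ValueError("accession_effect_sd is a fraction in [0, 1)")
        if self.elongation < 1.0:
            raise ValueError("elongation must be >= 1")
        r = self.size_correlation[0, 1]
        if not (-1.0 < r < 1.0):
            raise ValueError("size_correlation entries must lie in (-1, 1)")


def _chol(corr: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("infeasible size correlation matrix") from exc


def _seed_views(length, width, thickness, cd, cl, n_points):
    """Reconstruct both views at physical scale and re-derive normalized
    coefficients through the genuine forward pipeline."""
    a = length / 2.0
    out = []
    for semi_minor, cvec, base_coeffs in (
        (width / 2.0, cd, "dorsal"),
        (thickness / 2.0, cl, "lateral"),
    ):
        h = np.vstack([[a, 0.0, 0.0, semi_minor], (cvec * a).reshape(8, 4)])
        pts = eft_inverse(EFTCoefficients(harmonics=h), n_points)
        out.append(pts)
    dorsal_pts, lateral_pts = out
    nd = normalize(eft_forward(dorsal_pts, 9))
    nl = normalize(eft_forward(lateral_pts, 9))
    return dorsal_pts, lateral_pts, retained_vector(nd, nl)


def generate_population(
    templates, seed: int, n_points: int = 64, return_outlines: bool = False
):
    """Generate a full dataset from species templates.

    Deterministic under a fixed seed.  Returns a
    :class:`~seedmorph.dataio.Dataset` whose metadata carries the
    ground-truth labels; with ``return_outlines`` also returns the raw
    outline point arrays keyed by (seed_id, view).
    """
    templates = list(templates)
    if not templates:
        raise ValueError("need at least one template")
    rng = np.random.default_rng(seed)
    meas_rows, coeff_rows, meta_rows = [], [], []
    outlines = {}
    for tpl in templates:
        L_corr = _chol(np.asarray(tpl.size_correlation, dtype=float))
        sigma_tot = np.sqrt(np.log1p(np.square(tpl.size_cv)))
        f = tpl.accession_effect_sd
        sigma_b = f * sigma_tot
        sigma_w = np.sqrt(1.0 - f * f) * sigma_tot
        mu = np.log(tpl.size_means) - 0.5 * sigma_tot**2
        accs = tpl.accessions or [
            (f"{tpl.name[:3].upper()}{i + 1:02d}", tpl.seeds_per_accession)
            for i in range(tpl.n_accessions)
        ]
        for sample_id, n_seeds in accs:
            meta_rows.append(
                {
                    "sample_id": sample_id, "species": tpl.name, "status": tpl.status,
                    "role": tpl.role, "n_seeds": n_seeds, "origin": "", "label": "",
                }
            )
            acc_size = (L_corr @ rng.normal(size=3)) * sigma_b
            if tpl.role == "seedling":
                # seed-grown cultivated palms carry cultivar-typical sizes:
                # their individual effect is strongly shrunk toward the group
                acc_size *= 0.1
            acc_mode = rng.normal(0.0, tpl.mode_accession_sd, _N_MODES)
            for j in range(n_seeds):
                logs = mu + acc_size + (L_corr @ rng.normal(size=3)) * sigma_w
                length, width, thickness = np.exp(logs)
                width = min(width, 0.98 * length)
                sd = tpl.mode_scores + acc_mode + rng.normal(0.0, tpl.mode_within_sd, _N_MODES)
                sl = tpl.mode_scores + acc_mode + rng.normal(0.0, tpl.mode_within_sd, _N_MODES)
                cd = (
                    _BASE_DORSAL
                    + tpl.egg_asymmetry * np.eye(32)[0]
                    + _MODES_DORSAL @ sd
                    + rng.normal(size=32) * tpl.shape_noise_sd * _DECAY
                )
                cl = (
                    _BASE_LATERAL
                    + _MODES_LATERAL @ sl
                    + rng.normal(size=32) * tpl.shape_noise_sd * _DECAY
                )
                dpts, lpts, vec = _seed_views(length, width, thickness, cd, cl, n_points)
                seed_id = f"{sample_id}-D{j + 1}"
                meas_rows.append(
                    {
                        "seed_id": seed_id, "sample_id": sample_id,
                        "species": tpl.name, "status": tpl.status, "role": tpl.role,
                        "accession": sample_id,
                        "length": length, "width": width, "thickness": thickness,
                        "surface": polygon_area(dpts),
                    }
                )
                coeff_rows.append(pd.Series(vec, index=COEFF_COLUMNS, name=seed_id))
                if return_outlines:
                    outlines[(seed_id, "dorsal")] = dpts
                    outlines[(seed_id, "lateral")] = lpts
    measures = pd.DataFrame(meas_rows)
    coeffs = pd.DataFrame(coeff_rows)
    coeffs.index.name = "seed_id"
    metadata = pd.DataFrame(meta_rows)
    ds = Dataset(measures, coeffs, metadata)
    ds.templates = templates
    return (ds, outlines) if return_outlines else ds


# ---------------------------------------------------------------------------
# Calibrated reference panel

# (length, width, thickness) means and sds in cm, per species, and shape-mode
# scores placing each species in the shared deformation space.  Mode scores
# encode the reported inter-species affinities: sylvestris is the closest
# wild species to the date palm; acaulis/loureiroi/reclinata are mutually
# confusable; paludosa, caespitosa, canariensis and roebelenii stand apart.
_PANEL = {
    "acaulis": dict(means=(1.01, 0.58, 0.51), sds=(0.12, 0.06, 0.07),
                    scores=(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)),
    "andamanensis": dict(means=(1.41, 0.75, 0.66), sds=(0.06, 0.03, 0.03),
                         scores=(1.0, 1.5, 1.0, 0.3, -0.8, 0.6)),
    "caespitosa": dict(means=(1.18, 0.87, 0.77), sds=(0.11, 0.07, 0.06),
                       scores=(-2.0, 1.0, 1.8, -1.2, -0.8, -0.6)),
    "canariensis": dict(means=(1.51, 0.95, 0.89), sds=(0.16, 0.10, 0.09),
                        scores=(-1.8, -1.0, 1.5, 1.5, 0.9, -0.8)),
    "loureiroi": dict(means=(1.05, 0.61, 0.55), sds=(0.13, 0.05, 0.04),
                      scores=(0.6, 0.3, -0.2, 0.0, 0.2, 0.0)),
    "paludosa": dict(means=(0.99, 0.69, 0.54), sds=(0.08, 0.06, 0.05),
                     scores=(-2.5, -2.0, -1.5, -1.0, -1.2, 1.0)),
    "pusilla": dict(means=(0.95, 0.58, 0.52), sds=(0.12, 0.08, 0.08),
                    scores=(0.9, -0.9, 0.5, 0.5, -0.4, 0.0)),
    "reclinata": dict(means=(1.16, 0.70, 0.63), sds=(0.31, 0.12, 0.12),
                      scores=(-0.4, 0.6, 0.4, -0.3, 0.0, 0.2)),
    "roebelenii": dict(means=(0.80, 0.43, 0.35), sds=(0.03, 0.02, 0.02),
                       scores=(1.8, 2.2, -1.8, -1.5, 1.2, 1.5)),
    "rupicola": dict(means=(1.44, 0.74, 0.71), sds=(0.15, 0.05, 0.06),
                     scores=(1.5, -1.2, 1.2, -0.8, 0.6, 0.8)),
    "sylvestris": dict(means=(1.65, 0.92, 0.83), sds=(0.20, 0.10, 0.08),
                       scores=(2.2, 1.2, -0.6, 0.8, 0.5, -0.3)),
    "theophrasti": dict(means=(1.33, 0.76, 0.72), sds=(0.18, 0.08, 0.07),
                        scores=(-1.2, -1.5, -1.2, 0.6, 1.0, 0.4)),
}

# the dactylifera status groups: cultivated seeds are longer, elongated and
# highly variable; feral seeds keep a near-cultivated shape at reduced size;
# the unknown-status (Oman) seeds converge toward the wild morphotype.
_DACTYLIFERA = {
    "cultivated": dict(means=(2.16, 0.86, 0.78), sds=(0.44, 0.10, 0.10),
                       scores=(3.4, 1.8, -1.0, 1.2, 0.8, -0.5),
                       corr=_CORR_CULT, mode_within=1.3, mode_acc=1.2),
    "feral": dict(means=(1.70, 0.80, 0.72), sds=(0.20, 0.08, 0.08),
                  scores=(3.1, 1.65, -0.9, 1.1, 0.7, -0.45),
                  corr=_CORR_CULT, mode_within=1.0, mode_acc=0.5),
    "uncultivated_unknown": dict(means=(1.45, 0.75, 0.68), sds=(0.15, 0.07, 0.07),
                                 scores=(2.0, 1.05, -0.55, 0.75, 0.45, -0.3),
                                 corr=_CORR_WILD, mode_within=1.0, mode_acc=0.5),
}

#: within-accession coefficient of variation for sizes; the small value is
#: what makes per-accession means stabilize near 20 seeds under a 2.5% band
_WITHIN_CV = 0.07


def _split_fraction(cv_total: float) -> float:
    """Between-accession share of the sd so the within part is ~_WITHIN_CV."""
    if cv_total <= _WITHIN_CV:
        return 0.0
    return float(np.sqrt(1.0 - (_WITHIN_CV / cv_total) ** 2))


def phoenix_templates() -> list[SpeciesTemplate]:
    """The calibrated 13-species reference panel templates, one per wild
    species plus three dactylifera status groups, with the accession
    structure of the bundled metadata (85 samples, 1625 seeds)."""
    meta = load_bundled_metadata()
    templates: list[SpeciesTemplate] = []
    for species, cal in _PANEL.items():
        rows = meta[meta["species"] == species]
        cv = tuple(np.asarray(cal["sds"]) / np.asarray(cal["means"]))
        templates.append(
            SpeciesTemplate(
                name=species,
                status="wild_reference",
                size_means=cal["means"],
                size_cv=cv,
                size_correlation=_CORR_WILD.copy(),
                elongation=cal["means"][0] / cal["means"][1],
                accession_effect_sd=_split_fraction(cv[0]),
                mode_scores=np.asarray(cal["scores"]),
                role="wild",
                accessions=list(zip(rows["sample_id"], rows["n_seeds"])),
            )
        )
    dact = meta[meta["species"] == "dactylifera"]
    for status, cal in _DACTYLIFERA.items():
        rows = dact[dact["status"] == status]
        cv = tuple(np.asarray(cal["sds"]) / np.asarray(cal["means"]))
        for role in sorted(rows["role"].unique()):
            sel = rows[rows["role"] == role]
            templates.append(
                SpeciesTemplate(
                    name="dactylifera",
                    status=status,
                    size_means=cal["means"],
                    size_cv=cv,
                    size_correlation=cal["corr"].copy(),
                    elongation=cal["means"][0] / cal["means"][1],
                    accession_effect_sd=_split_fraction(cv[0]),
                    mode_scores=np.asarray(cal["scores"]),
                    mode_within_sd=cal["mode_within"],
                    mode_accession_sd=cal["mode_acc"],
                    role=role,
                    accessions=list(zip(sel["sample_id"], sel["n_seeds"])),
                )
            )
    return templates


def paper_like_panel(seed: int, n_points: int = 64) -> Dataset:
    """A ready-made multi-species panel sized like the reference study
    (13 species, 85 accessions, 1625 seeds), with cultivated date palms
    long/elongated/highly variable and wild species small/rounded with
    tightly coupled size parameters."""
    return generate_population(phoenix_templates(), seed=seed, n_points=n_points)
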