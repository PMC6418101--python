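"""Synthetic screening and expression data with recorded ground truth.

Every generator in this module emulates one data stream of a primary-fibroblast
RNAi screen against the myofibroblast marker ASMA (alpha smooth muscle actin):

* :func:`simulate_screen` — well-level ASMA score tables for multi-donor plates
  carrying negative-control (GFP shRNA), positive-control (ACTA2 shRNA) and
  test-shRNA wells.
* :func:`simulate_knockdown_panel` — qPCR-style relative target expression for
  an shRNA panel whose true knockdown efficacies are drawn from a calibrated
  mixture.
* :func:`render_well_image` — two-channel (DAPI, ASMA) 16-bit well images with
  known nucleus count and per-cell stain level.
* :func:`simulate_expression_study` — log2 expression matrices with a planted
  disease signature, partial attenuation at passage 4, and a two-batch
  location/scale batch effect with replicate samples bridging the batches.

All outputs are deterministic functions of their config (including the seed)
and come with a :class:`GroundTruth` record so downstream estimates can be
checked against the quantities that generated them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class ConfigurationError(ValueError):
    """Raised when a generator config violates its invariants."""


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed at the requested separation."""


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

NEG_CONTROL_ID = "shGFP"
POS_CONTROL_ID = "shACTA2"

ROLE_NEG = "negative_control"
ROLE_POS = "positive_control"
ROLE_TEST = "test"


@dataclass(frozen=True)
class EfficacyMixture:
    """Two-component model of shRNA knockdown efficacy in [0, 1].

    A fraction ``w_eff`` of shRNAs are efficacious with efficacy drawn from a
    normal truncated to [0, 1]; the remainder are poor silencers drawn
    uniformly from [0, ``ineff_max``].
    """

    w_eff: float = 0.8
    eff_mean: float = 0.84
    eff_sd: float = 0.10
    ineff_max: float = 0.6

    def validate(self) -> None:
        if not 0.0 < self.w_eff <= 1.0:
            raise ConfigurationError(f"w_eff must be in (0, 1], got {self.w_eff}")
        if self.eff_sd < 0:
            raise ConfigurationError("eff_sd must be >= 0")
        if not 0.0 < self.ineff_max <= 1.0:
            raise ConfigurationError("ineff_max must be in (0, 1]")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` efficacies; always in [0, 1]."""
        self.validate()
        is_eff = rng.random(n) < self.w_eff
        out = np.empty(n)
        n_eff = int(is_eff.sum())
        if self.eff_sd == 0:
            out[is_eff] = np.clip(self.eff_mean, 0.0, 1.0)
        else:
            a = (0.0 - self.eff_mean) / self.eff_sd
            b = (1.0 - self.eff_mean) / self.eff_sd
            out[is_eff] = stats.truncnorm.rvs(
                a, b, loc=self.eff_mean, scale=self.eff_sd,
                size=n_eff, random_state=rng,
            )
        out[~is_eff] = rng.uniform(0.0, self.ineff_max, size=n - n_eff)
        return out

    def tail_probability(self, threshold: float) -> float:
        """Closed-form P(efficacy > threshold) under the mixture."""
        if self.eff_sd == 0:
            p_eff = float(self.eff_mean > threshold)
        else:
            a = (0.0 - self.eff_mean) / self.eff_sd
            b = (1.0 - self.eff_mean) / self.eff_sd
            p_eff = stats.truncnorm.sf(
                threshold, a, b, loc=self.eff_mean, scale=self.eff_sd
            )
        p_ineff = max(0.0, 1.0 - threshold / self.ineff_max) if threshold < self.ineff_max else 0.0
        return self.w_eff * float(p_eff) + (1.0 - self.w_eff) * p_ineff


@dataclass(frozen=True)
class ScreenConfig:
    """Design of a multi-donor ASMA screen.

    ``fold_separation`` is the true ratio of negative-control to
    positive-control mean well score (the generative assay window);
    ``cv_noise`` the lognormal coefficient of variation of well scores.
    Test-shRNA well means follow ``1 - efficacy * (1 - 1/fold_separation)``
    scaled by a per-donor lognormal random effect of sd ``donor_effect_sd``.
    """

    n_donors: int = 2
    wells_per_condition: int = 120
    fold_separation: float = 3.0
    cv_noise: float = 0.10
    shrna_panel: tuple[tuple[str, int], ...] = ()
    efficacy_model: EfficacyMixture = field(default_factory=EfficacyMixture)
    donor_effect_sd: float = 0.1
    measurement_cv: float = 0.05
    transduction_offset: float = 0.0
    nuclei_mean: float = 180.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_donors < 1:
            raise ConfigurationError("n_donors must be >= 1")
        if self.wells_per_condition < 2:
            raise ConfigurationError("wells_per_condition must be >= 2")
        if self.fold_separation <= 1:
            raise ConfigurationError(
                f"fold_separation must exceed 1, got {self.fold_separation}"
            )
        if self.cv_noise < 0:
            raise ConfigurationError("cv_noise must be >= 0")
        if self.measurement_cv < 0:
            raise ConfigurationError("measurement_cv must be >= 0")
        if self.donor_effect_sd < 0:
            raise ConfigurationError("donor_effect_sd must be >= 0")
        for gene, k in self.shrna_panel:
            if not 2 <= k <= 8:
                raise ConfigurationError(
                    f"panel gene {gene!r} has {k} shRNAs; expected 2-8"
                )
        self.efficacy_model.validate()


def uniform_panel(n_genes: int, shrnas_per_gene: int = 4) -> tuple[tuple[str, int], ...]:
    """Convenience panel of ``n_genes`` genes with equal shRNA counts."""
    return tuple((f"G{i:04d}", shrnas_per_gene) for i in range(n_genes))


@dataclass(frozen=True)
class ImageSpec:
    """Rendering parameters for a synthetic two-channel well field.

    Nuclei are compact radial-Gaussian spots (support truncated at
    ``nucleus_radius``); ASMA fibres are elongated anisotropic Gaussian
    strokes anchored at each nucleus.  Amplitudes are in 16-bit AU.
    """

    shape: tuple[int, int] = (256, 256)
    bit_depth: int = 16
    nucleus_radius: int = 6
    nucleus_amplitude: float = 20000.0
    asma_length: int = 48
    asma_width: int = 4
    asma_amplitude: float = 4000.0
    background: float = 400.0
    poisson_noise: bool = True
    read_noise_sd: float = 8.0
    min_separation: int = 16

    def validate(self, require_disjoint: bool = False) -> None:
        vmax = 2 ** self.bit_depth - 1
        if not 0 <= self.background <= vmax:
            raise ConfigurationError("background outside bit depth range")
        if self.background + self.nucleus_amplitude > vmax:
            raise ConfigurationError("nucleus amplitude clips at this bit depth")
        if self.nucleus_radius < 1:
            raise ConfigurationError("nucleus_radius must be >= 1")
        if require_disjoint and self.min_separation <= 2 * self.nucleus_radius:
            raise ConfigurationError(
                "min_separation must exceed 2 * nucleus_radius for disjoint nuclei"
            )


@dataclass(frozen=True)
class StudyConfig:
    """Design of the two-passage, two-batch expression study.

    ``retention_fraction`` is the fraction of signature probes whose disease
    effect persists in full at passage 4; the rest shrink to
    ``attenuation_residual`` of their baseline log2 fold change.  The batch
    model is the location/scale model the correction assumes: an additive
    per-(probe, batch) shift and a multiplicative scale on the residual.
    """

    n_probes: int = 2000
    n_signature: int = 200
    effect_range: tuple[float, float] = (0.6, 2.0)
    retention_fraction: float = 0.77
    attenuation_residual: float = 0.25
    n_ssc: int = 8
    n_healthy: int = 8
    n_replicates: int = 9
    batch_shift_sd: float = 0.3
    batch_scale_range: tuple[float, float] = (0.8, 1.25)
    noise_sd: float = 0.25
    baseline_mean_range: tuple[float, float] = (5.0, 12.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_signature > self.n_probes:
            raise ConfigurationError("n_signature must be <= n_probes")
        if not 0.0 <= self.retention_fraction <= 1.0:
            raise ConfigurationError("retention_fraction must be in [0, 1]")
        if min(self.n_ssc, self.n_healthy) < 3:
            raise ConfigurationError("need at least 3 samples per group")
        if self.n_replicates < 1:
            raise ConfigurationError("need >= 1 replicate sample in both batches")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.batch_shift_sd < 0:
            raise ConfigurationError("batch_shift_sd must be >= 0")
        lo, hi = self.batch_scale_range
        if not 0 < lo <= hi:
            raise ConfigurationError("batch_scale_range must be 0 < lo <= hi")


@dataclass
class GroundTruth:
    """Truth records for one simulated dataset; unused fields stay None."""

    well_truth: pd.DataFrame | None = None
    donor_effects: pd.DataFrame | None = None
    shrna_efficacy: pd.DataFrame | None = None
    probe_truth: pd.DataFrame | None = None
    sample_truth: pd.DataFrame | None = None
    nuclei_centers: np.ndarray | None = None
    nucleus_mask: np.ndarray | None = None


# ---------------------------------------------------------------------------
# screen simulation
# ---------------------------------------------------------------------------

def _lognormal_factors(cv: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative noise with unit mean and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=size))


def simulate_screen(
    config: ScreenConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate per-well ASMA scores for a multi-donor control + test screen.

    Returns ``(plate_map, well_table, truth)``.  The plate map has one row per
    well with columns ``plate, well, donor, shrna_id, gene, role``; the well
    table mirrors it with the quantified readout ``density, area, nuclei,
    score`` where score = density * area / nuclei.  Negative-control wells
    have mean score 1.0, positive controls ``1/fold_separation``, and each
    test shRNA ``1 - efficacy * (1 - 1/fold_separation)`` times the donor's
    random effect.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_eff, ss_donor, ss_wells = root.spawn(3)

    eff_rng = np.random.default_rng(ss_eff)
    shrna_ids: list[str] = []
    genes: list[str] = []
    for gene, k in config.shrna_panel:
        for j in range(1, k + 1):
            shrna_ids.append(f"sh{gene}_{j}")
            genes.append(gene)
    efficacies = config.efficacy_model.sample(len(shrna_ids), eff_rng)

    donor_rng = np.random.default_rng(ss_donor)
    donors = [f"D{i + 1:02d}" for i in range(config.n_donors)]
    if config.donor_effect_sd == 0:
        donor_fx = np.ones(config.n_donors)
    else:
        donor_fx = np.exp(
            donor_rng.normal(
                -0.5 * config.donor_effect_sd ** 2,
                config.donor_effect_sd,
                size=config.n_donors,
            )
        )

    inv_fold = 1.0 / config.fold_separation
    conditions: list[tuple[str, str, str, float | None]] = [
        (NEG_CONTROL_ID, "GFP", ROLE_NEG, None),
        (POS_CONTROL_ID, "ACTA2", ROLE_POS, None),
    ]
    for sid, gene, eff in zip(shrna_ids, genes, efficacies):
        conditions.append((sid, gene, ROLE_TEST, float(eff)))

    well_rng = np.random.default_rng(ss_wells)
    nw = config.wells_per_condition
    rows: list[dict] = []
    truth_rows: list[dict] = []
    for donor, dfx in zip(donors, donor_fx):
        plate = f"P_{donor}"
        widx = 0
        for sid, gene, role, eff in conditions:
            if role == ROLE_NEG:
                mu = 1.0
            elif role == ROLE_POS:
                mu = inv_fold
            else:
                mu = (1.0 - eff * (1.0 - inv_fold)) * dfx
            mu = mu + config.transduction_offset
            scores = mu * _lognormal_factors(config.cv_noise, nw, well_rng)
            nuclei = np.maximum(
                well_rng.poisson(config.nuclei_mean, size=nw), 1
            ).astype(int)
            # density in normalized AU chosen so areas land at realistic
            # field pixel counts; score = density * area / nuclei holds exactly
            density = 0.01 * _lognormal_factors(0.05 if config.cv_noise > 0 else 0.0, nw, well_rng)
            area = scores * nuclei / density
            for k in range(nw):
                widx += 1
                well = f"W{widx:04d}"
                rows.append(
                    dict(
                        plate=plate, well=well, donor=donor, shrna_id=sid,
                        gene=gene, role=role, density=density[k],
                        area=area[k], nuclei=nuclei[k], score=scores[k],
                    )
                )
                truth_rows.append(
                    dict(
                        plate=plate, well=well, donor=donor, shrna_id=sid,
                        true_mean_score=mu, true_nuclei=int(nuclei[k]),
                    )
                )

    full = pd.DataFrame(rows)
    plate_map = full[["plate", "well", "donor", "shrna_id", "gene", "role"]].copy()
    well_table = full[
        ["plate", "well", "donor", "density", "area", "nuclei", "score"]
    ].copy()
    truth = GroundTruth(
        well_truth=pd.DataFrame(truth_rows),
        donor_effects=pd.DataFrame({"donor": donors, "effect": donor_fx}),
        shrna_efficacy=pd.DataFrame(
            {"shrna_id": shrna_ids, "gene": genes, "efficacy": efficacies}
        ),
    )
    return plate_map, well_table, truth


def simulate_knockdown_panel(
    config: ScreenConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate qPCR relative target expression for the shRNA panel.

    Each shRNA's true efficacy is drawn once from the config's mixture; the
    observed relative expression in each donor is ``(1 - efficacy)`` times
    multiplicative lognormal measurement noise (CV ``measurement_cv``; 0
    disables noise).  Returns ``(panel, truth)`` where panel has one row per
    (shrna, donor) with column ``relative_expression``.
    """
    config.validate()
    if not config.shrna_panel:
        raise ConfigurationError("shrna_panel is empty")
    root = np.random.SeedSequence(config.seed)
    ss_eff, _, ss_meas = root.spawn(3)
    eff_rng = np.random.default_rng(ss_eff)

    shrna_ids: list[str] = []
    genes: list[str] = []
    for gene, k in config.shrna_panel:
        for j in range(1, k + 1):
            shrna_ids.append(f"sh{gene}_{j}")
            genes.append(gene)
    efficacies = config.efficacy_model.sample(len(shrna_ids), eff_rng)

    meas_rng = np.random.default_rng(ss_meas)
    donors = [f"D{i + 1:02d}" for i in range(config.n_donors)]
    rows = []
    for donor in donors:
        noise = _lognormal_factors(config.measurement_cv, len(shrna_ids), meas_rng)
        rel = (1.0 - efficacies) * noise
        for sid, gene, r in zip(shrna_ids, genes, rel):
            rows.append(
                dict(shrna_id=sid, gene=gene, donor=donor, relative_expression=r)
            )
    panel = pd.DataFrame(rows)
    truth = GroundTruth(
        shrna_efficacy=pd.DataFrame(
            {"shrna_id": shrna_ids, "gene": genes, "efficacy": efficacies}
        )
    )
    return panel, truth


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

def _place_centers(
    n: int, shape: tuple[int, int], margin: int, min_sep: float,
    rng: np.random.Generator, max_tries_per_center: int = 2000,
) -> np.ndarray:
    centers: list[np.ndarray] = []
    lo = np.array([margin, margin], dtype=float)
    hi = np.array([shape[0] - margin, shape[1] - margin], dtype=float)
    if np.any(hi <= lo):
        raise PlacementError("image too small for the requested margin")
    tries = 0
    while len(centers) < n:
        cand = rng.uniform(lo, hi)
        if all(np.hypot(*(cand - c)) >= min_sep for c in centers):
            centers.append(cand)
        else:
            tries += 1
            if tries > max_tries_per_center * n:
                raise PlacementError(
                    f"could not place {n} nuclei at separation {min_sep} "
                    f"in a {shape[0]}x{shape[1]} field"
                )
    return np.array(centers).reshape(n, 2)


def _add_radial_spot(
    img: np.ndarray, center: np.ndarray, radius: int, amplitude: float
) -> None:
    """Add a radial Gaussian spot truncated at ``radius`` (compact support)."""
    cy, cx = center
    y0, y1 = int(max(0, np.floor(cy - radius))), int(min(img.shape[0], np.ceil(cy + radius) + 1))
    x0, x1 = int(max(0, np.floor(cx - radius))), int(min(img.shape[1], np.ceil(cx + radius) + 1))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    sigma = radius / 2.5
    patch = amplitude * np.exp(-0.5 * r2 / sigma ** 2)
    patch[r2 > radius ** 2] = 0.0
    img[y0:y1, x0:x1] += patch


def _add_stroke(
    img: np.ndarray, center: np.ndarray, length: int, width: int,
    angle: float, amplitude: float,
) -> None:
    """Add an elongated anisotropic Gaussian stroke (a stress-fibre bundle)."""
    sl, sw = length / 6.0, width / 2.0
    half = int(np.ceil(length / 2 + 3 * sw)) + 1
    cy, cx = center
    y0, y1 = int(max(0, np.floor(cy - half))), int(min(img.shape[0], np.ceil(cy + half) + 1))
    x0, x1 = int(max(0, np.floor(cx - half))), int(min(img.shape[1], np.ceil(cx + half) + 1))
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(angle) + dy * np.sin(angle)
    v = -dx * np.sin(angle) + dy * np.cos(angle)
    patch = amplitude * np.exp(-0.5 * (u ** 2 / sl ** 2 + v ** 2 / sw ** 2))
    patch[np.abs(u) > length / 2 + 3 * sw] = 0.0
    img[y0:y1, x0:x1] += patch


def render_well_image(
    nuclei_count: int,
    asma_level: float,
    spec: ImageSpec = ImageSpec(),
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a two-channel (DAPI, ASMA) well field as a uint16 stack.

    The DAPI channel is a sum of compact radial Gaussian spots at random
    centers honouring ``spec.min_separation``; the ASMA channel places one
    elongated stroke per cell with amplitude ``spec.asma_amplitude *
    asma_level``.  Both channels sit on ``spec.background`` and, unless noise
    is disabled, receive shot (Poisson) plus Gaussian read noise.

    Returns ``(stack, truth)`` with ``stack.shape == (2, H, W)`` (channel
    order DAPI, ASMA) and truth carrying the centers and the noise-free
    nucleus mask.
    """
    if nuclei_count < 0:
        raise ConfigurationError("nuclei_count must be >= 0")
    if asma_level < 0:
        raise ConfigurationError("asma_level must be >= 0")
    spec.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    h, w = spec.shape
    dapi = np.full((h, w), float(spec.background))
    asma = np.full((h, w), float(spec.background))
    if nuclei_count > 0:
        margin = spec.nucleus_radius + 2
        centers = _place_centers(
            nuclei_count, spec.shape, margin, spec.min_separation, rng
        )
        angles = rng.uniform(0, np.pi, size=nuclei_count)
        for c, ang in zip(centers, angles):
            _add_radial_spot(dapi, c, spec.nucleus_radius, spec.nucleus_amplitude)
            if asma_level > 0:
                _add_stroke(
                    asma, c, spec.asma_length, spec.asma_width, ang,
                    spec.asma_amplitude * asma_level,
                )
    else:
        centers = np.zeros((0, 2))

    mask = dapi > spec.background  # noise-free truth mask

    vmax = 2 ** spec.bit_depth - 1
    stack = np.stack([dapi, asma])
    if spec.poisson_noise:
        stack = rng.poisson(stack).astype(float)
    if spec.read_noise_sd > 0:
        stack = stack + rng.normal(0.0, spec.read_noise_sd, size=stack.shape)
    stack = np.clip(np.rint(stack), 0, vmax).astype(np.uint16)

    truth = GroundTruth(nuclei_centers=centers, nucleus_mask=mask)
    return stack, truth


# ---------------------------------------------------------------------------
# expression study
# ---------------------------------------------------------------------------

def simulate_expression_study(
    config: StudyConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the two-batch, two-passage disease-signature study.

    Returns ``(matrix, meta, truth)``.  ``matrix`` is probes x samples of log2
    intensities; ``meta`` has columns ``sample_id, donor, disease, passage,
    batch, replicate_of``.  Signature probes carry a disease effect (uniform
    magnitude in ``effect_range``, random sign) at baseline; at passage 4 a
    fraction ``retention_fraction`` keep the full effect and the rest shrink
    to ``attenuation_residual`` of it.  Batch effects follow the
    location/scale model: additive per-(probe, batch) shift ~
    N(0, batch_shift_sd) and residual scale ~ U(batch_scale_range).
    Replicate samples share their source sample's biology and differ only in
    batch terms and residual noise.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_truth, ss_batch, ss_noise = root.spawn(3)
    trng = np.random.default_rng(ss_truth)

    n_probes = config.n_probes
    probes = np.array([f"probe_{i:05d}" for i in range(n_probes)])
    baseline = trng.uniform(*config.baseline_mean_range, size=n_probes)

    sig_idx = trng.choice(n_probes, size=config.n_signature, replace=False)
    sig_idx.sort()
    magnitudes = trng.uniform(*config.effect_range, size=config.n_signature)
    signs = trng.choice([-1.0, 1.0], size=config.n_signature)
    lfc_base = np.zeros(n_probes)
    lfc_base[sig_idx] = magnitudes * signs

    n_retained = int(round(config.retention_fraction * config.n_signature))
    retained_local = trng.choice(config.n_signature, size=n_retained, replace=False)
    retained_mask_local = np.zeros(config.n_signature, dtype=bool)
    retained_mask_local[retained_local] = True
    lfc_p4 = np.zeros(n_probes)
    lfc_p4[sig_idx[retained_mask_local]] = lfc_base[sig_idx[retained_mask_local]]
    lfc_p4[sig_idx[~retained_mask_local]] = (
        config.attenuation_residual * lfc_base[sig_idx[~retained_mask_local]]
    )

    # biological samples: disease x passage groups
    samples: list[dict] = []
    bio_lfc: list[np.ndarray] = []
    for passage, lfc in (("P0P1", lfc_base), ("P4", lfc_p4)):
        for disease, n in (("SSc", config.n_ssc), ("healthy", config.n_healthy)):
            for i in range(n):
                sid = f"{disease}{i + 1:02d}_{passage}"
                samples.append(
                    dict(
                        sample_id=sid, donor=f"{disease}{i + 1:02d}",
                        disease=disease, passage=passage, replicate_of="",
                    )
                )
                bio_lfc.append(lfc if disease == "SSc" else np.zeros(n_probes))

    n_bio = len(samples)
    # alternate batches within each group so batch is never confounded
    batches = np.array([1 + (i % 2) for i in range(n_bio)])
    # replicate samples: copies of the first n_replicates biological samples,
    # assigned to the opposite batch
    rep_sources = list(range(min(config.n_replicates, n_bio)))
    for j, src in enumerate(rep_sources):
        samples.append(
            dict(
                sample_id=f"{samples[src]['sample_id']}_rep",
                donor=samples[src]["donor"],
                disease=samples[src]["disease"],
                passage=samples[src]["passage"],
                replicate_of=samples[src]["sample_id"],
            )
        )
        bio_lfc.append(bio_lfc[src])
        batches = np.append(batches, 3 - batches[src])

    n_samples = len(samples)
    meta = pd.DataFrame(samples)
    meta["batch"] = batches

    brng = np.random.default_rng(ss_batch)
    gamma = (
        brng.normal(0.0, config.batch_shift_sd, size=(n_probes, 2))
        if config.batch_shift_sd > 0
        else np.zeros((n_probes, 2))
    )
    lo, hi = config.batch_scale_range
    delta = (
        brng.uniform(lo, hi, size=(n_probes, 2)) if hi > lo
        else np.full((n_probes, 2), lo)
    )

    nrng = np.random.default_rng(ss_noise)
    eps = nrng.normal(0.0, config.noise_sd, size=(n_probes, n_samples))
    y = np.empty((n_probes, n_samples))
    for s in range(n_samples):
        b = batches[s] - 1
        y[:, s] = baseline + bio_lfc[s] + gamma[:, b] + delta[:, b] * eps[:, s]

    matrix = pd.DataFrame(y, index=probes, columns=meta["sample_id"].to_numpy())
    sig_mask = np.zeros(n_probes, dtype=bool)
    sig_mask[sig_idx] = True
    retained = np.zeros(n_probes, dtype=bool)
    retained[sig_idx[retained_mask_local]] = True
    truth = GroundTruth(
        probe_truth=pd.DataFrame(
            {
                "probe": probes, "baseline_mean": baseline,
                "lfc_baseline": lfc_base, "lfc_p4": lfc_p4,
                "is_signature": sig_mask, "is_retained": retained,
            }
        ),
        sample_truth=meta.copy(),
    )
    return matrix, meta, truth


def config_to_json(config) -> dict:
    """Echo any generator config as a JSON-serialisable dict."""
    d = dataclasses.asdict(config)

    def _clean(v):
        if isinstance(v, tuple):
            return [_clean(x) for x in v]
        if isinstance(v, dict):
            return {k: _clean(x) for k, x in v.items()}
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        return v

    return _clean(d)
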