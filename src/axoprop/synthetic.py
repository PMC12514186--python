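"""Synthetic-data generators with planted ground truth.

Every input the analysis pipeline consumes can be generated here under the
default study conditions: 4 replicates per each of mouse/jerboa × TV1/TV6,
negative-binomial counts with species-specific transcript lengths, a planted
linear relation between the TV1 and TV6 interspecies log2 fold changes with
disproportionate outliers, crescendo-decrescendo tail phantoms, and
growth-plate cell tables. Each generator is a pure function of its
configuration, including the seed.

Group means are parameterized from a single per-gene ground truth so that
the three contrasts of the intersection analysis are mutually consistent::

    mouse TV1  = baseline
    mouse TV6  = baseline + delta_vert
    jerboa TV1 = baseline + lfc_TV1
    jerboa TV6 = baseline + delta_vert + lfc_TV6

from which the intra-jerboa TV6-vs-TV1 log2FC is
``delta_vert + lfc_TV6 - lfc_TV1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _defaults as dflt

SPECIES = ("mouse", "jerboa")
VERTEBRAE = ("TV1", "TV6")
GENE_CLASSES = ("null", "equivalent", "A_type", "B_type")


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Fan a master seed out into ``n`` independent per-stage seeds (< 2^31)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for the count simulation.

    Fractions partition genes into classes: ``equivalent`` genes share a
    species effect between TV1 and TV6 (up to scatter about the planted
    line), ``A_type`` genes are DE between species in TV6 only, ``B_type``
    genes are DE in both vertebrae with a disproportionate extra TV6
    residual, and the remainder are null.
    """

    n_genes: int = 2000
    n_reps: int = dflt.N_REPS
    baseline_log_mean: float = dflt.BASELINE_LOG_MEAN
    baseline_log_sd: float = dflt.BASELINE_LOG_SD
    dispersion: float | np.ndarray = dflt.DISPERSION
    frac_equivalent: float = dflt.FRAC_EQUIVALENT
    frac_A: float = dflt.FRAC_A
    frac_B: float = dflt.FRAC_B
    slope_b: float = dflt.SLOPE
    intercept_a: float = dflt.INTERCEPT
    resid_sd: float = dflt.RESID_SD
    outlier_sd: float = dflt.OUTLIER_SD
    x_sd: float = dflt.X_SD
    a_effect: tuple[float, float] = dflt.A_EFFECT
    b_x_effect: tuple[float, float] = dflt.B_X_EFFECT
    delta_vert: float = 0.0
    length_log_sd: float = dflt.LENGTH_LOG_SD
    size_factor_range: tuple[float, float] = dflt.SIZE_FACTOR_RANGE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        total = self.frac_equivalent + self.frac_A + self.frac_B
        if total > 1.0 + 1e-12:
            raise ValueError("class fractions must sum to <= 1")
        for name in ("resid_sd", "outlier_sd", "baseline_log_sd",
                     "length_log_sd", "x_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if np.any(np.asarray(self.dispersion) < 0):
            raise ValueError("dispersion must be >= 0")


@dataclass
class PhantomConfig:
    """Geometry of a 1D µCT tail phantom.

    ``true_lengths`` are diaphysis lengths in µm, cranial to caudal; when
    omitted, a species-default neonatal profile (sequentially shorter from
    TV1) is used. The effective pixel is ``voxel * resize`` µm.
    """

    species: str = "jerboa"
    n_vertebrae: int | None = None
    true_lengths: np.ndarray | None = None
    gap: float = dflt.GAP_UM
    naso_anal: float | None = None
    voxel: float = dflt.VOXEL_UM
    resize: int = dflt.RESIZE
    intensity_noise_sd: float = 0.0
    ossified_mask: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}")
        if self.n_vertebrae is None:
            self.n_vertebrae = dflt.N_VERTEBRAE[self.species]
        if self.true_lengths is None:
            self.true_lengths = neonate_length_profile(
                self.species, self.n_vertebrae)
        self.true_lengths = np.asarray(self.true_lengths, dtype=float)
        if len(self.true_lengths) != self.n_vertebrae:
            raise ValueError("true_lengths length must equal n_vertebrae")
        if np.any(self.true_lengths <= 0) or self.gap <= 0:
            raise ValueError("lengths and gap must be > 0")
        if self.voxel * self.resize <= 0:
            raise ValueError("voxel * resize must be > 0")
        if self.ossified_mask is None:
            self.ossified_mask = np.ones(self.n_vertebrae, dtype=bool)
        self.ossified_mask = np.asarray(self.ossified_mask, dtype=bool)
        if self.naso_anal is None:
            self.naso_anal = dflt.NASO_ANAL_UM[self.species][0]

    @property
    def pixel_um(self) -> float:
        return self.voxel * self.resize


# ---------------------------------------------------------------------------
# ortholog table
# ---------------------------------------------------------------------------

def simulate_ortholog_table(n_genes: int,
                            length_log_sd: float = dflt.LENGTH_LOG_SD,
                            seed: int = 0,
                            frac_one_to_zero: float = dflt.FRAC_ONE_TO_ZERO,
                            ) -> pd.DataFrame:
    """Simulate an ortholog table with per-species transcript lengths.

    Mouse lengths are log-normal around 2 kb; jerboa lengths are the mouse
    length times ``exp(N(0, length_log_sd^2))``. About ``frac_one_to_zero``
    of genes are flagged one-to-zero and lack a jerboa length (the orthology
    class of genes predicted lost or unannotated in one species).

    Returns a DataFrame indexed by ``gene_id`` with columns
    ``orthology_class``, ``length_mouse``, ``length_jerboa``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    length_mouse = dflt.MEDIAN_LENGTH_BP * np.exp(
        rng.normal(0.0, dflt.LENGTH_BASE_SD, n_genes))
    ratio = np.exp(rng.normal(0.0, length_log_sd, n_genes))
    length_jerboa = length_mouse * ratio
    n_zero = int(round(frac_one_to_zero * n_genes))
    one_to_zero = np.zeros(n_genes, dtype=bool)
    if n_zero:
        one_to_zero[rng.choice(n_genes, size=n_zero, replace=False)] = True
    length_jerboa = np.where(one_to_zero, np.nan, length_jerboa)
    return pd.DataFrame(
        {"orthology_class": np.where(one_to_zero, "one_to_zero", "one_to_one"),
         "length_mouse": length_mouse,
         "length_jerboa": length_jerboa},
        index=pd.Index(genes, name="gene_id"))


# ---------------------------------------------------------------------------
# counts + ground truth
# ---------------------------------------------------------------------------

def _draw_ground_truth(config: SimConfig, genes: Sequence[str],
                       rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_genes
    n_eq = int(round(config.frac_equivalent * n))
    n_a = int(round(config.frac_A * n))
    n_b = int(round(config.frac_B * n))
    classes = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    classes[order[:n_eq]] = "equivalent"
    classes[order[n_eq:n_eq + n_a]] = "A_type"
    classes[order[n_eq + n_a:n_eq + n_a + n_b]] = "B_type"

    lfc_tv1 = np.zeros(n)
    lfc_tv6 = np.zeros(n)
    eq = classes == "equivalent"
    a = classes == "A_type"
    b = classes == "B_type"

    x_eq = rng.normal(0.0, config.x_sd, int(eq.sum()))
    lfc_tv1[eq] = x_eq
    lfc_tv6[eq] = (config.intercept_a + config.slope_b * x_eq
                   + rng.normal(0.0, config.resid_sd, int(eq.sum())))

    mu_a, sd_a = config.a_effect
    lfc_tv6[a] = (rng.choice([-1.0, 1.0], int(a.sum()))
                  * rng.normal(mu_a, sd_a, int(a.sum())))

    mu_bx, sd_bx = config.b_x_effect
    x_b = rng.choice([-1.0, 1.0], int(b.sum())) * rng.normal(
        mu_bx, sd_bx, int(b.sum()))
    extra = rng.choice([-1.0, 1.0], int(b.sum())) * rng.normal(
        config.outlier_sd, config.resid_sd, int(b.sum()))
    lfc_tv1[b] = x_b
    lfc_tv6[b] = config.intercept_a + config.slope_b * x_b + extra

    truth = pd.DataFrame(
        {"gene_class": classes,
         "lfc_TV1": lfc_tv1,
         "lfc_TV6": lfc_tv6,
         "delta_vert": np.full(n, config.delta_vert)},
        index=pd.Index(genes, name="gene_id"))
    truth["lfc_intra"] = (truth["delta_vert"] + truth["lfc_TV6"]
                          - truth["lfc_TV1"])
    return truth


def sample_metadata(n_reps: int = dflt.N_REPS) -> pd.DataFrame:
    """The 2 species × 2 vertebrae × n_reps sample sheet of the design."""
    rows = [
        {"sample_id": f"{sp}_{vert}_r{r + 1}", "species": sp,
         "vertebra": vert, "replicate": r + 1}
        for sp in SPECIES for vert in VERTEBRAE for r in range(n_reps)
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_counts(config: SimConfig,
                    ortholog_table: pd.DataFrame | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a gene × sample NB count matrix with planted ground truth.

    The mean for gene g in sample j is
    ``s_j * (L_{g,species(j)} / geomean(L_g)) * 2^(baseline_g + effect)``
    with the four group effects read off the ground truth, and counts are
    negative binomial with dispersion alpha (Poisson when alpha = 0).
    Sample size factors ``s_j`` are drawn uniformly from
    ``config.size_factor_range``.

    Returns ``(counts, metadata, truth)``; the truth table records each
    gene's class, planted log2FCs and baseline.
    """
    seeds = spawn_seeds(config.seed, 4)
    if ortholog_table is None:
        ortholog_table = simulate_ortholog_table(
            config.n_genes, config.length_log_sd, seed=seeds[0])
    if len(ortholog_table) != config.n_genes:
        raise ValueError("ortholog_table size does not match n_genes")
    genes = list(ortholog_table.index)

    rng_truth = np.random.default_rng(seeds[1])
    truth = _draw_ground_truth(config, genes, rng_truth)
    rng = np.random.default_rng(seeds[2])
    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd,
                          config.n_genes)
    truth["baseline_log2"] = baseline

    meta = sample_metadata(config.n_reps)
    lo, hi = config.size_factor_range
    size_factors = rng.uniform(lo, hi, len(meta))

    # per-gene log2 group means
    group_log2 = {
        ("mouse", "TV1"): baseline,
        ("mouse", "TV6"): baseline + truth["delta_vert"].to_numpy(),
        ("jerboa", "TV1"): baseline + truth["lfc_TV1"].to_numpy(),
        ("jerboa", "TV6"): (baseline + truth["delta_vert"].to_numpy()
                            + truth["lfc_TV6"].to_numpy()),
    }

    lm = ortholog_table["length_mouse"].to_numpy(dtype=float)
    lj = ortholog_table["length_jerboa"].to_numpy(dtype=float)
    lj_eff = np.where(np.isnan(lj), lm, lj)     # one-to-zero: ratio 1
    geomean_len = np.sqrt(lm * lj_eff)
    length_ratio = {"mouse": lm / geomean_len, "jerboa": lj_eff / geomean_len}

    alpha = np.broadcast_to(np.asarray(config.dispersion, dtype=float),
                            (config.n_genes,)).copy()
    counts = np.empty((config.n_genes, len(meta)), dtype=np.int64)
    for j, (sid, row) in enumerate(meta.iterrows()):
        mu = (size_factors[j]
              * length_ratio[row["species"]]
              * 2.0 ** group_log2[(row["species"], row["vertebra"])])
        counts[:, j] = _nb_draw(rng, mu, alpha)

    counts_df = pd.DataFrame(counts, index=truth.index, columns=meta.index)
    return counts_df, meta, truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             alpha: np.ndarray) -> np.ndarray:
    """NB(mean mu, dispersion alpha) draws; Poisson where alpha ~ 0."""
    out = np.empty_like(mu, dtype=np.int64)
    poisson = alpha < 1e-9
    if poisson.any():
        out[poisson] = rng.poisson(mu[poisson])
    nb = ~poisson
    if nb.any():
        size = 1.0 / alpha[nb]
        p = size / (size + mu[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


def true_candidate_set(truth: pd.DataFrame) -> set[str]:
    """Planted disproportionate genes: A/B-class genes whose intra-jerboa
    log2FC shares the sign of their interspecies TV6 log2FC (the ground-truth
    analogue of the pipeline's final sign-consistent candidate set)."""
    disp = truth["gene_class"].isin(["A_type", "B_type"])
    consistent = (np.sign(truth["lfc_TV6"]) == np.sign(truth["lfc_intra"])) \
        & (truth["lfc_TV6"] != 0)
    return set(truth.index[disp & consistent])


# ---------------------------------------------------------------------------
# paired log2FC fixture
# ---------------------------------------------------------------------------

def simulate_lfc_pairs(n: int = dflt.N_PAIRS,
                       a: float = dflt.INTERCEPT,
                       b: float = dflt.SLOPE,
                       resid_sd: float = dflt.RESID_SD,
                       frac_outlier: float = dflt.FRAC_OUTLIER,
                       outlier_sd: float = dflt.OUTLIER_SD,
                       x_sd: float = dflt.X_SD,
                       seed: int = 0) -> pd.DataFrame:
    """Paired (TV1, TV6) log2FCs: inliers on ``y = a + b x`` with Gaussian
    scatter, plus a planted fraction of disproportionate outliers carrying an
    extra ``±N(outlier_sd, resid_sd^2)`` residual.

    Returns a DataFrame with columns ``x``, ``y``, ``is_outlier``.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, x_sd, n)
    y = a + b * x + rng.normal(0.0, resid_sd, n)
    n_out = int(round(frac_outlier * n))
    is_out = np.zeros(n, dtype=bool)
    if n_out:
        idx = rng.choice(n, size=n_out, replace=False)
        is_out[idx] = True
        extra = rng.choice([-1.0, 1.0], n_out) * rng.normal(
            outlier_sd, resid_sd, n_out)
        y[idx] += extra
    return pd.DataFrame({"x": x, "y": y, "is_outlier": is_out})


# ---------------------------------------------------------------------------
# tail phantoms
# ---------------------------------------------------------------------------

def neonate_length_profile(species: str, n_vertebrae: int | None = None
                           ) -> np.ndarray:
    """Neonatal diaphysis lengths (µm), sequentially shorter from TV1."""
    if n_vertebrae is None:
        n_vertebrae = dflt.N_VERTEBRAE[species]
    i = np.arange(n_vertebrae)
    return dflt.NEONATE_TV1_UM[species] * np.exp(-i / dflt.NEONATE_DECAY)


def simulate_tail_phantom(config: PhantomConfig
                          ) -> tuple[pd.DataFrame, np.ndarray]:
    """Render a 1D intensity profile along the tail axis.

    Each ossified diaphysis is a high plateau flanked by 1-pixel linear edge
    ramps at half height, so the half-height midpoint rule recovers the
    planted width exactly: an element of k pixels is rendered as a (k-1)-pixel
    plateau plus one ramp pixel on each side, whose half-height crossings are
    exactly k pixels apart. Unossified elements and inter-vertebral gaps are
    background. Additive Gaussian noise with sd ``intensity_noise_sd``.

    Returns ``(profile, true_lengths_um)`` where profile has columns
    ``pixel_index`` and ``intensity``.
    """
    px = config.pixel_um
    lengths_px = np.round(config.true_lengths / px).astype(int)
    if np.any(lengths_px < 2):
        raise ValueError("every element must span at least 2 effective pixels")
    gap_px = max(2, int(round(config.gap / px)))
    lead = 5

    hi, lo = dflt.BONE_INTENSITY, dflt.BACKGROUND_INTENSITY
    mid = 0.5 * (hi + lo)
    segments: list[np.ndarray] = [np.full(lead, lo)]
    for k, (lpx, ossified) in enumerate(
            zip(lengths_px, config.ossified_mask)):
        if ossified:
            segments.append(np.concatenate([
                [mid], np.full(lpx - 1, hi), [mid]]))
        else:
            segments.append(np.full(lpx + 1, lo))
        segments.append(np.full(gap_px, lo))
    segments.append(np.full(lead, lo))
    values = np.concatenate(segments)

    if config.intensity_noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        values = values + rng.normal(0.0, config.intensity_noise_sd,
                                     len(values))
    profile = pd.DataFrame({"pixel_index": np.arange(len(values)),
                            "intensity": values})
    return profile, config.true_lengths.copy()


# ---------------------------------------------------------------------------
# growth series
# ---------------------------------------------------------------------------

def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _growth_weights(n_vertebrae: int) -> np.ndarray:
    """Crescendo-decrescendo allocation of postnatal tail growth, peaking at
    TV6 with a plateau over roughly TV5-TV8."""
    i = np.arange(1, n_vertebrae + 1, dtype=float)
    w = np.exp(-((i - dflt.PEAK_VERTEBRA_CENTER) / dflt.PEAK_VERTEBRA_WIDTH)
               ** 2)
    return w / w.sum()


def simulate_growth_series(species: str = "mouse",
                           n_animals: int = 3,
                           noise_sd: float = 0.02,
                           seed: int = 0,
                           timepoints: Sequence[int] = dflt.TIMEPOINTS_DAYS,
                           ) -> pd.DataFrame:
    """Per-animal, per-vertebra length series over weekly timepoints P0-P42.

    The naso-anal length grows monotonically from birth to adult size; the
    tail:body ratio starts near 0.5 at birth in both species and rises (after
    ~P7) to the species' adult value (mouse ~1.0, jerboa 1.5); postnatal tail
    growth is distributed across vertebrae with a crescendo-decrescendo pulse
    peaking at TV6. Animal-level noise is a time-constant multiplicative
    factor per animal and per vertebra, so every series remains monotone
    non-decreasing in time.

    Returns a tidy frame with columns ``animal, time_days, vertebra,
    length_um, naso_anal_um, species``.
    """
    if species not in SPECIES:
        raise ValueError(f"species must be one of {SPECIES}")
    t = np.asarray(timepoints, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    n_vert = dflt.N_VERTEBRAE[species]
    n0, n_ad = dflt.NASO_ANAL_UM[species]
    r0 = dflt.NEONATE_TAIL_RATIO
    r_ad = dflt.ADULT_TAIL_RATIO[species]
    t_max = t[-1]

    # monotone body growth and a ratio trajectory flat through the first week
    naso = n0 + (n_ad - n0) * _smoothstep(t / t_max)
    ratio = r0 + (r_ad - r0) * _smoothstep((t - 7.0) / (t_max - 7.0))
    total_tail = ratio * naso

    base = neonate_length_profile(species, n_vert)
    base = base * (r0 * n0) / base.sum()        # tail:body exactly r0 at P0
    w = _growth_weights(n_vert)
    growth_total = total_tail[-1] - total_tail[0]
    phi = (total_tail - total_tail[0]) / growth_total   # monotone 0 -> 1

    rng = np.random.default_rng(seed)
    records = []
    for a in range(n_animals):
        animal = f"{species}_{a + 1}"
        scale = max(0.1, 1.0 + rng.normal(0.0, noise_sd)) if noise_sd > 0 \
            else 1.0
        vert_jitter = (1.0 + rng.normal(0.0, noise_sd, n_vert)
                       if noise_sd > 0 else np.ones(n_vert))
        vert_jitter = np.clip(vert_jitter, 0.1, None)
        for k, tk in enumerate(t):
            lengths = (base + w * growth_total * phi[k]) * vert_jitter * scale
            na = naso[k] * scale
            for v in range(n_vert):
                records.append((animal, float(tk), v + 1,
                                float(lengths[v]), float(na), species))
    return pd.DataFrame(records, columns=[
        "animal", "time_days", "vertebra", "length_um", "naso_anal_um",
        "species"])


# ---------------------------------------------------------------------------
# growth plates
# ---------------------------------------------------------------------------

@dataclass
class GrowthPlateConfig:
    """Configured laws for the histomorphometry generator."""

    n_specimens: int = 8
    n_sections: int = 3
    n_cells_per_section: int = 120
    zone_means: dict = field(default_factory=lambda: dict(dflt.ZONE_MEANS_UM))
    zone_cv: float = dflt.ZONE_CV
    cell_height: tuple[float, float] = dflt.CELL_HEIGHT_UM
    edu_p: float = dflt.EDU_P
    daily_rate_um: float = dflt.DAILY_RATE_UM
    rate_noise_sd: float = 2.0
    elapsed_hours: float = dflt.CALCEIN_HOURS
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.zone_means.values()):
            raise ValueError("zone means must be >= 0")
        if self.cell_height[0] < 0 or self.daily_rate_um < 0:
            raise ValueError("configured means must be >= 0")
        if not 0.0 <= self.edu_p <= 1.0:
            raise ValueError("edu_p must be in [0, 1]")


def simulate_growth_plate(config: GrowthPlateConfig
                          ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate growth-plate section tables.

    Zone heights and cell heights are normal draws around the configured
    means; EdU labels are Bernoulli(``edu_p``) per cell; the calcein-front
    distance is ``elapsed_hours/24 × daily_rate`` plus noise (48 h after the
    pulse, the distance is twice the daily elongation rate).

    Returns ``(sections, cells, truth)``: one row per section with zone
    heights, EdU counts and calcein distance; one row per cell with its
    height and EdU label; and the planted parameter dict.
    """
    rng = np.random.default_rng(config.seed)
    sec_rows, cell_rows = [], []
    for s in range(config.n_specimens):
        for sec in range(config.n_sections):
            zones = {f"{z}_um": max(0.0, rng.normal(m, config.zone_cv * m))
                     for z, m in config.zone_means.items()}
            heights = np.clip(
                rng.normal(*config.cell_height, config.n_cells_per_section),
                0.1, None)
            edu = rng.random(config.n_cells_per_section) < config.edu_p
            dist = (config.elapsed_hours / 24.0) * config.daily_rate_um
            if config.rate_noise_sd > 0:
                dist += rng.normal(0.0, config.rate_noise_sd)
            sec_rows.append({"specimen": f"sp{s + 1}", "section": sec + 1,
                             **zones,
                             "edu_positive": int(edu.sum()),
                             "edu_total": int(len(edu)),
                             "calcein_front_um": max(0.0, dist)})
            for h, e in zip(heights, edu):
                cell_rows.append({"specimen": f"sp{s + 1}",
                                  "section": sec + 1,
                                  "cell_height_um": float(h),
                                  "edu_positive": bool(e)})
    truth = {"edu_p": config.edu_p, "daily_rate_um": config.daily_rate_um,
             "zone_means": dict(config.zone_means),
             "cell_height": config.cell_height,
             "elapsed_hours": config.elapsed_hours}
    return pd.DataFrame(sec_rows), pd.DataFrame(cell_rows), truth


# ---------------------------------------------------------------------------
# writers (TSV/CSV, UTF-8, "." decimal)
# ---------------------------------------------------------------------------

def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t")


def write_ortholog_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def write_ground_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t")


def write_profile(profile: pd.DataFrame, path) -> None:
    profile.to_csv(path, index=False)
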