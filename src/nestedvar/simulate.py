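"""Paired-platform simulator for the nested 2x2x2x2 expression experiment.

Generates a microarray arm (two-channel log2 ratios with intensity-flat
chip noise by default) and a sequencing arm (per-lane read counts whose
sampling noise grows as per-gene depth falls) from one shared ground
truth, so that every downstream stage — normalization, differential
expression, variance decomposition, concordance, enrichment — can be
tested against known per-gene effects and variance components.

The model on the log2 scale for gene g in sample s is

    x_gs = a_g + c_s * beta_g / 2 + b_(g, bio(s)) + p_(g, prep(s)) + e_gs

where ``a_g`` is the baseline log2 abundance, ``c_s`` is +1 in condition
G and -1 in condition E (so the G-vs-E contrast of x is the log2(G/E)
fold change ``beta_g``), ``b`` and ``p`` are biological-replicate and
preparation random effects, and ``e_gs`` is the platform unit noise:
Gaussian chip noise for arrays, a lognormal lane factor followed by
Poisson (or multinomial) read sampling for sequencing.

Optional low-intensity systematic biases (additive log-FC offsets on one
platform) emulate probe-specific artifacts such as cross-hybridization;
a small qPCR simulator produces replicate Ct tables for validation-style
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .io_design import ExpressionMatrix, NestedDesign, canonical_design

__all__ = [
    "BiasSpec",
    "SimulationParams",
    "GroundTruth",
    "simulate_truth",
    "simulate_counts",
    "simulate_two_channel",
    "simulate_qpcr",
    "simulate_experiment",
    "flat_fraction_params",
    "intensity_dependent_array_sigma",
]

LOG2_SQ = np.log(2.0) ** 2  # delta-method constant for var(log2 Poisson)


@dataclass(frozen=True)
class BiasSpec:
    """Systematic low-intensity bias on one platform.

    ``n_genes`` genes are drawn from the bottom ``max_quantile`` of
    baseline abundance and given an additive log2 fold-change offset of
    magnitude ``offset_location + |N(0, offset_sd)|`` with random sign,
    applied to the named platform only.  With ``prefer_de`` (default)
    the affected genes are drawn from the low-abundance genes that carry
    a true condition effect, emulating validation candidates that show
    genuine fold changes on the unbiased platform; if too few exist the
    pool falls back to all low-abundance genes.
    """

    platform: str = "array"  # 'array' or 'counts'
    n_genes: int = 13
    max_quantile: float = 0.2
    offset_location: float = 1.5
    offset_sd: float = 0.5
    prefer_de: bool = True

    def __post_init__(self) -> None:
        if self.platform not in ("array", "counts"):
            raise ValueError("bias platform must be 'array' or 'counts'")
        if not 0 < self.max_quantile <= 1:
            raise ValueError("max_quantile must be in (0, 1]")


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the paired-platform simulation.

    All standard deviations are on the log2 scale.  The defaults are a
    desk-scale rendition of the yeast carbon-source experiment: 5000
    genes with a wide log-normal abundance distribution (log2 sd 2.5,
    several orders of magnitude of expression), 20% of genes
    differentially expressed with N(0, 1) log2 fold changes, small
    intensity-flat biological and preparation variation, intensity-flat
    chip noise on the array arm, and a flat lane factor plus Poisson
    read sampling (1M reads per lane, about a tenth of the study's
    depth) on the sequencing arm.  The chip noise floor (sd 0.305) sits
    fractionally above the lane's flat component (sd 0.30) by exactly
    the residual sampling variance of the highest-depth decile at this
    reduced scale, so the two platforms add equivalent noise for
    high-depth genes while the sequencing arm becomes markedly noisier
    as depth falls — the intensity-dependence regime of the original
    experiment.
    """

    n_genes: int = 5000
    design: NestedDesign = field(default_factory=canonical_design)
    baseline_log_abundance: tuple[float, float] = (4.0, 2.5)  # mean, sd of a_g
    prop_de: float = 0.2
    de_logfc: tuple[float, float] = (0.0, 1.0)  # mean, sd of beta_g | DE
    de_balanced_signs: bool = False  # force exactly half of DE genes up
    sigma_bio: float = 0.2
    sigma_prep: float = 0.2
    array_sigma_unit: float | Callable[[np.ndarray], np.ndarray] = 0.305
    seq_total_reads: int = 1_000_000
    seq_extra_sigma_unit: float = 0.30
    ref_sigma: float = 0.05  # per-gene noise of the common reference channel
    array_fluor_scale: float = 30.0
    bias_spec: BiasSpec | None = None
    count_scheme: str = "poisson"  # or 'multinomial'
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not 0.0 <= self.prop_de <= 1.0:
            raise ValueError("prop_de must be in [0, 1]")
        for name in ("sigma_bio", "sigma_prep", "seq_extra_sigma_unit", "ref_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not callable(self.array_sigma_unit) and self.array_sigma_unit < 0:
            raise ValueError("array_sigma_unit must be >= 0")
        if self.seq_total_reads <= 0:
            raise ValueError("seq_total_reads must be positive")
        if self.count_scheme not in ("poisson", "multinomial"):
            raise ValueError("count_scheme must be 'poisson' or 'multinomial'")

    def array_unit_sd(self, a: np.ndarray) -> np.ndarray:
        """Per-gene chip noise sd, evaluated at baseline log2 abundance."""
        if callable(self.array_sigma_unit):
            sd = np.asarray(self.array_sigma_unit(a), dtype=float)
            if sd.shape != a.shape or (sd < 0).any():
                raise ValueError("array_sigma_unit callable must map a_g to sd >= 0")
            return sd
        return np.full_like(a, float(self.array_sigma_unit))


def flat_fraction_params(
    fractions: tuple[float, float, float, float] = (0.5, 0.1, 0.1, 0.3),
    total_var: float = 1.0,
    n_genes: int = 5000,
    seq_total_reads: int = 2_000_000,
    baseline_sd: float = 1.0,
    seed: int = 0,
) -> SimulationParams:
    """Parameters giving every gene the same true variance fractions.

    The four fractions are (condition, biological, preparation, unit).
    Every gene is differentially expressed with |beta| fixed so that the
    condition stage contributes ``fractions[0]`` of the total log2
    variance; signs are balanced so the condition effect survives
    compositional (per-lane total) normalization of the counts.  The
    sequencing depth is raised so Poisson sampling noise is negligible
    next to the flat lane factor, keeping the count platform's unit
    fraction intensity-flat as well.
    """
    f = np.asarray(fractions, dtype=float)
    if f.shape != (4,) or (f < 0).any() or not np.isclose(f.sum(), 1.0):
        raise ValueError("fractions must be 4 nonnegative values summing to 1")
    beta = 2.0 * np.sqrt(f[0] * total_var)
    return SimulationParams(
        n_genes=n_genes,
        baseline_log_abundance=(6.0, baseline_sd),
        prop_de=1.0,
        de_logfc=(beta, 0.0),
        de_balanced_signs=True,
        sigma_bio=float(np.sqrt(f[1] * total_var)),
        sigma_prep=float(np.sqrt(f[2] * total_var)),
        array_sigma_unit=float(np.sqrt(f[3] * total_var)),
        seq_extra_sigma_unit=float(np.sqrt(f[3] * total_var)),
        seq_total_reads=seq_total_reads,
        ref_sigma=0.0,
        seed=seed,
    )


def intensity_dependent_array_sigma(
    floor: float = 0.15, scale: float = 0.5, halving: float = 2.0
) -> Callable[[np.ndarray], np.ndarray]:
    """Chip noise sd that decays with baseline abundance.

    Returns ``a -> floor + scale * 2**(-a / halving)``: a mild
    low-intensity rise in array noise, for experiments that probe the
    within-platform fold-change divergence as a function of intensity
    (real chips are noisier at low fluorescence, just much less so than
    lanes are at low depth).
    """

    def sigma(a: np.ndarray) -> np.ndarray:
        return floor + scale * np.exp2(-np.asarray(a, dtype=float) / halving)

    return sigma


@dataclass
class GroundTruth:
    """Realized simulation truth shared by both platform simulators."""

    params: SimulationParams
    genes: pd.Index
    a: pd.Series  # baseline log2 abundance
    beta: pd.Series  # condition log2(G/E) fold change
    bio_effects: pd.DataFrame  # genes x biological replicates
    prep_effects: pd.DataFrame  # genes x preparations
    array_unit_noise: pd.DataFrame  # genes x samples
    seq_unit_log2: pd.DataFrame  # genes x samples, lane overdispersion
    ref_effects: pd.Series  # per-gene reference-channel offset
    bias_array: pd.Series  # additive log-FC offsets, array platform
    bias_counts: pd.Series  # additive log-FC offsets, count platform

    @property
    def design(self) -> NestedDesign:
        return self.params.design

    def condition_sign(self) -> pd.Series:
        """+1 for condition G-like (first sorted label is E-like -1)."""
        cond = self.design.condition_of()
        hi = self.design.conditions[1] if len(self.design.conditions) > 1 else None
        # convention: the *second* sorted label plays the role of G (numerator)
        return cond.map(lambda c: 1.0 if c == hi else -1.0)

    def expected_mean_count(self) -> pd.Series:
        """Approximate expected per-sample read count per gene."""
        w = np.exp2(self.a.to_numpy())
        p = w / w.sum()
        return pd.Series(p * self.params.seq_total_reads, index=self.genes)

    def true_fractions(self, platform: str) -> pd.DataFrame:
        """Per-gene variance fractions implied by the parameters.

        For the count platform the unit component adds the delta-method
        log2-scale Poisson sampling variance 1/(mu * ln(2)^2) at the
        gene's expected depth to the flat lane-factor variance.
        """
        v_cond = self.beta.to_numpy() ** 2 / 4.0
        v_bio = np.full_like(v_cond, self.params.sigma_bio**2)
        v_prep = np.full_like(v_cond, self.params.sigma_prep**2)
        if platform == "array":
            v_unit = self.params.array_unit_sd(self.a.to_numpy()) ** 2
        elif platform == "counts":
            mu = self.expected_mean_count().to_numpy()
            v_unit = self.params.seq_extra_sigma_unit**2 + 1.0 / (mu * LOG2_SQ)
        else:
            raise ValueError("platform must be 'array' or 'counts'")
        comp = np.column_stack([v_cond, v_bio, v_prep, v_unit])
        total = comp.sum(axis=1)
        total[total == 0] = np.nan
        frac = comp / total[:, None]
        return pd.DataFrame(
            frac,
            index=self.genes,
            columns=["condition", "biological", "preparation", "residual"],
        )


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stream])


def simulate_truth(params: SimulationParams) -> GroundTruth:
    """Draw the shared ground truth. Deterministic given ``params.seed``."""
    rng = _rng(params.seed, 0)
    genes = pd.Index([f"g{i:05d}" for i in range(params.n_genes)], name="gene")
    design = params.design
    mu_a, sd_a = params.baseline_log_abundance
    a = rng.normal(mu_a, sd_a, params.n_genes)

    beta = np.zeros(params.n_genes)
    n_de = int(round(params.prop_de * params.n_genes))
    de_idx = rng.choice(params.n_genes, size=n_de, replace=False)
    if n_de:
        mu_b, sd_b = params.de_logfc
        draws = rng.normal(mu_b, sd_b, n_de)
        if params.de_balanced_signs:
            signs = np.ones(n_de)
            signs[: n_de // 2] = -1.0
            rng.shuffle(signs)
            draws = np.abs(draws) * signs
        draws[draws == 0.0] = 1e-6  # DE genes must have a nonzero effect
        beta[de_idx] = draws

    bios = sorted(design.table["biological"].unique())
    preps = sorted(design.table["preparation"].unique())
    samples = design.samples
    bio_effects = pd.DataFrame(
        rng.normal(0.0, params.sigma_bio, (params.n_genes, len(bios)))
        if params.sigma_bio > 0
        else np.zeros((params.n_genes, len(bios))),
        index=genes,
        columns=bios,
    )
    prep_effects = pd.DataFrame(
        rng.normal(0.0, params.sigma_prep, (params.n_genes, len(preps)))
        if params.sigma_prep > 0
        else np.zeros((params.n_genes, len(preps))),
        index=genes,
        columns=preps,
    )
    arr_sd = params.array_unit_sd(a)
    array_unit_noise = pd.DataFrame(
        rng.normal(0.0, 1.0, (params.n_genes, len(samples))) * arr_sd[:, None],
        index=genes,
        columns=samples,
    )
    seq_unit_log2 = pd.DataFrame(
        rng.normal(0.0, params.seq_extra_sigma_unit, (params.n_genes, len(samples)))
        if params.seq_extra_sigma_unit > 0
        else np.zeros((params.n_genes, len(samples))),
        index=genes,
        columns=samples,
    )
    ref_effects = pd.Series(
        rng.normal(0.0, params.ref_sigma, params.n_genes)
        if params.ref_sigma > 0
        else np.zeros(params.n_genes),
        index=genes,
    )

    bias_array = pd.Series(np.zeros(params.n_genes), index=genes)
    bias_counts = pd.Series(np.zeros(params.n_genes), index=genes)
    if params.bias_spec is not None:
        spec = params.bias_spec
        order = np.argsort(a, kind="stable")
        low = order[: int(np.ceil(spec.max_quantile * params.n_genes))]
        if spec.prefer_de:
            de_low = low[beta[low] != 0.0]
            if len(de_low) >= spec.n_genes:
                low = de_low
        chosen = rng.choice(low, size=min(spec.n_genes, len(low)), replace=False)
        mags = spec.offset_location + np.abs(rng.normal(0.0, spec.offset_sd, len(chosen)))
        signs = rng.choice([-1.0, 1.0], size=len(chosen))
        target = bias_array if spec.platform == "array" else bias_counts
        target.iloc[chosen] = mags * signs

    return GroundTruth(
        params=params,
        genes=genes,
        a=pd.Series(a, index=genes),
        beta=pd.Series(beta, index=genes),
        bio_effects=bio_effects,
        prep_effects=prep_effects,
        array_unit_noise=array_unit_noise,
        seq_unit_log2=seq_unit_log2,
        ref_effects=ref_effects,
        bias_array=bias_array,
        bias_counts=bias_counts,
    )


def _shared_signal(truth: GroundTruth, bias: pd.Series) -> np.ndarray:
    """Gene x sample log2 signal shared by both platforms (+ platform bias)."""
    design = truth.design
    t = design.table
    c = truth.condition_sign().loc[t["sample"]].to_numpy()  # +-1 per sample
    a = truth.a.to_numpy()[:, None]
    eff = (truth.beta.to_numpy()[:, None] + bias.to_numpy()[:, None]) * c[None, :] / 2.0
    bio = truth.bio_effects[t["biological"].to_numpy()].to_numpy()
    prep = truth.prep_effects[t["preparation"].to_numpy()].to_numpy()
    return a + eff + bio + prep


def simulate_counts(truth: GroundTruth, params: SimulationParams | None = None) -> ExpressionMatrix:
    """Simulate the sequencing arm as per-lane read counts.

    Per-gene expected proportions within each lane are proportional to
    2**(signal + lane factor); reads are drawn either as independent
    Poisson variates whose expectations sum to the lane total (default)
    or as one multinomial draw per lane.
    """
    params = params or truth.params
    rng = _rng(params.seed, 3)
    x = _shared_signal(truth, truth.bias_counts) + truth.seq_unit_log2.to_numpy()
    w = np.exp2(x)
    p = w / w.sum(axis=0, keepdims=True)
    if params.count_scheme == "poisson":
        counts = rng.poisson(p * params.seq_total_reads)
    else:
        counts = np.column_stack(
            [rng.multinomial(params.seq_total_reads, p[:, j]) for j in range(p.shape[1])]
        )
    values = pd.DataFrame(counts, index=truth.genes, columns=truth.design.samples)
    return ExpressionMatrix(values, "counts")


def simulate_two_channel(truth: GroundTruth, params: SimulationParams | None = None) -> ExpressionMatrix:
    """Simulate the microarray arm as log2(red/green) ratios.

    The green (reference) channel is modeled as the per-gene mean of the
    two condition means plus its own small per-gene noise, so the ratio
    retains the condition contrast and the chip noise.  The per-gene
    intensity summary is the baseline abundance rescaled to a
    fluorescence-like range.
    """
    params = params or truth.params
    x = _shared_signal(truth, truth.bias_array)
    ref = truth.a.to_numpy()[:, None] + truth.ref_effects.to_numpy()[:, None]
    m = (x - ref) + truth.array_unit_noise.to_numpy()
    values = pd.DataFrame(m, index=truth.genes, columns=truth.design.samples)
    intensity = pd.Series(
        params.array_fluor_scale * np.exp2(truth.a.to_numpy()), index=truth.genes
    )
    return ExpressionMatrix(values, "logratio", intensity)


def simulate_qpcr(
    truth: GroundTruth,
    genes,
    n_reps: int = 3,
    sigma_ct: float = 0.15,
    seed: int | None = None,
    ct_intercept: float = 30.0,
    plate_sigma: float = 0.3,
) -> pd.DataFrame:
    """Simulate replicate RT-qPCR Ct values for selected genes.

    Ct is inversely linear in log2 abundance (one PCR cycle per log2
    unit, lower Ct = more abundant).  Measurements are taken on the four
    biological RNA samples, ``n_reps`` replicates each; every (sample,
    replicate) run carries a shared plate offset which the downstream
    per-replicate all-gene centering removes.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in truth.genes]
    if missing:
        raise KeyError(f"genes not in simulation truth: {missing}")
    params = truth.params
    rng = _rng(params.seed if seed is None else seed, 7)
    t = truth.design.table.drop_duplicates("biological")
    sign = {
        row.biological: (1.0 if row.condition == truth.design.conditions[-1] else -1.0)
        for row in t.itertuples()
    }
    rows = []
    for bio, s in sign.items():
        cond = t.loc[t["biological"] == bio, "condition"].iloc[0]
        for rep in range(1, n_reps + 1):
            plate = rng.normal(0.0, plate_sigma) if plate_sigma > 0 else 0.0
            for g in genes:
                x = (
                    truth.a[g]
                    + s * truth.beta[g] / 2.0
                    + truth.bio_effects.at[g, bio]
                )
                noise = rng.normal(0.0, sigma_ct) if sigma_ct > 0 else 0.0
                rows.append((g, bio, cond, rep, ct_intercept - x + plate + noise))
    return pd.DataFrame(
        rows, columns=["gene", "biological", "condition", "replicate", "ct"]
    )


def simulate_experiment(params: SimulationParams):
    """Convenience wrapper: truth plus both platform matrices."""
    truth = simulate_truth(params)
    return truth, simulate_counts(truth), simulate_two_channel(truth)


def simulate_gene_sets(
    intensity: pd.Series,
    n_sets: int = 200,
    set_size: tuple[int, int] = (25, 60),
    window: int = 400,
    seed: int = 0,
    prefix: str = "S",
):
    """Random gene sets that are coherent in expression intensity.

    Functional gene sets in real data tend to share expression levels
    (ribosomal sets are abundant, signalling sets scarce), which is what
    makes intensity confounding of enrichment possible.  Each simulated
    set draws its members from a window of ``window`` genes contiguous
    in the intensity ordering, at a uniformly random position; set sizes
    are uniform over ``set_size``.  Membership carries no relationship
    to the condition effect, so the sets are enrichment-null.
    """
    from .io_design import GeneSet, GeneSetCollection

    rng = np.random.default_rng([int(seed) % (2**31), 13])
    order = pd.Series(intensity).sort_values(kind="stable").index.to_numpy()
    n = len(order)
    window = min(window, n)
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(set_size[0], set_size[1] + 1))
        start = int(rng.integers(0, n - window + 1))
        members = rng.choice(order[start : start + window], size=size, replace=False)
        name = f"{prefix}{i:04d}"
        sets[name] = GeneSet(name, f"intensity-coherent null set {i}", tuple(members))
    return GeneSetCollection(sets)
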