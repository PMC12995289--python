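"""Synthetic 2x2 factorial RNA-seq count generator with planted regulation archetypes.

The generator emulates a dual-stimulus study design: a dietary factor
(``Ctrl`` vs ``MetR``, methionine restriction) crossed with an ambient
temperature factor (``RT`` vs ``CE``, cold exposure), with balanced
replication per cell.  Counts are drawn from a negative-binomial model

    count_gj ~ NB(mean = sf_j * 2**(beta0_g + x_diet*b_diet + x_temp*b_temp
                                    + x_diet*x_temp*b_int),
                  var  = mu + alpha * mu**2)

where ``x_diet = 1`` for MetR samples and ``x_temp = 1`` for cold-exposed
samples.  Each gene carries a planted *archetype* — a canonical sign pattern
of (b_diet, b_temp, b_int) that, evaluated noise-free, lands in exactly one
of the downstream regulation categories (co-dependent, concordant,
discordant, dominant, masked, ...).  The emitted truth table makes every
pipeline stage verifiable without external data.

Contrast naming convention used throughout the package: A is the
temperature-only contrast (Ctrl_CE vs Ctrl_RT), B the diet-only contrast
(MetR_RT vs Ctrl_RT), AB the combined contrast (MetR_CE vs Ctrl_RT), and
INT the diet x temperature interaction coefficient.  Hence on the log2
scale the planted analogues are  l2fc_A = b_temp,  l2fc_B = b_diet,
l2fc_AB = b_temp + b_diet + b_int,  l2fc_INT = b_int.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DIET_LEVELS = ("Ctrl", "MetR")
TEMPERATURE_LEVELS = ("RT", "CE")
GROUPS = ("Ctrl_RT", "Ctrl_CE", "MetR_RT", "MetR_CE")

#: All planted regulation archetypes, in canonical order.
ARCHETYPES = (
    "null",
    "A_only",
    "B_only",
    "concordant_additive",
    "co_dependent",
    "discordant",
    "A_dominant",
    "B_dominant",
    "A_masked",
    "B_masked",
    "mutually_masked",
    "synergistic",
    "antagonistic",
)

#: Regulation category each archetype should receive when its exact planted
#: log2 fold changes are fed through the classifier (``None`` = excluded:
#: no contrast ever reaches significance).  A_only/B_only genes respond to a
#: single stimulus, so the combined response "follows" that stimulus and the
#: classifier files them as dominant; purely synergistic/antagonistic genes
#: have concordant single responses and are distinguished by synergy class.
EXPECTED_CATEGORY = {
    "null": None,
    "A_only": "A_dominant",
    "B_only": "B_dominant",
    "concordant_additive": "concordant",
    "co_dependent": "co_dependent",
    "discordant": "discordant",
    "A_dominant": "A_dominant",
    "B_dominant": "B_dominant",
    "A_masked": "A_masked",
    "B_masked": "B_masked",
    "mutually_masked": "mutually_masked",
    "synergistic": "concordant",
    "antagonistic": "concordant",
}

#: Synergy class each archetype should receive noise-free at the default
#: effect size (interaction magnitude >= the call threshold where listed as
#: synergistic/antagonistic).  Masked archetypes have l2fc_AB == 0 exactly,
#: so the score (a log of a ratio with zero numerator) is undefined.
EXPECTED_SYNERGY_CLASS = {
    "null": None,
    "A_only": "additive",
    "B_only": "additive",
    "concordant_additive": "additive",
    "co_dependent": "synergistic",
    "discordant": "antagonistic",
    "A_dominant": "additive",
    "B_dominant": "additive",
    "A_masked": "undefined",
    "B_masked": "undefined",
    "mutually_masked": "additive",
    "synergistic": "synergistic",
    "antagonistic": "antagonistic",
}


def archetype_betas(archetype: str, effect_size: float, sign: int = 1):
    """Canonical (beta_diet, beta_temp, beta_int) pattern for an archetype.

    Patterns are expressed in units of ``effect_size`` e.  ``sign`` (+1/-1)
    mirrors the whole pattern, so both induced and repressed variants of each
    archetype exist.  The co_dependent pattern uses sixth-effect singles,
    (e/6, e/6, e): the category is defined by a significance pattern
    (significant only under the combined stimulus), so its planted singles
    must sit well below the magnitude call threshold — far enough that
    sampling noise at n=7/group rarely pushes an observed single past the
    cutoff — while the combined effect (4e/3) sits well above it.  This was
    calibrated empirically at the default conditions (e=1.5, alpha=0.05
    dispersion): singles of 0.25 log2 units are called in <~5% of genes,
    singles of 0.375 (a quarter effect) in ~15%, which is enough to tip a
    co-dependent gene into a dominant call through one spurious single.
    """
    e = float(effect_size)
    s = int(sign)
    if s not in (-1, 1):
        raise ValueError("sign must be +1 or -1")
    patterns = {
        "null": (0.0, 0.0, 0.0),
        "A_only": (0.0, e, 0.0),
        "B_only": (e, 0.0, 0.0),
        "concordant_additive": (e, e, 0.0),
        "co_dependent": (e / 6, e / 6, e),
        "discordant": (e, e, -3 * e),
        "A_dominant": (-e / 2, e, 0.0),
        "B_dominant": (e, -e / 2, 0.0),
        "A_masked": (0.0, e, -e),
        "B_masked": (e, 0.0, -e),
        "mutually_masked": (e, -e, 0.0),
        "synergistic": (e, e, e),
        "antagonistic": (e, e, -e / 2),
    }
    try:
        bd, bt, bi = patterns[archetype]
    except KeyError:
        raise ValueError(f"unknown archetype: {archetype!r}") from None
    return (s * bd, s * bt, s * bi)


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with its attached sample design.

    ``counts`` is a genes x samples DataFrame (index = gene ids, columns =
    sample ids); ``design`` has one row per sample with columns
    ``sample_id``, ``diet``, ``temperature`` and optionally ``size_factor``.
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    truth: pd.DataFrame | None = field(default=None)

    def __post_init__(self):
        if not self.counts.index.is_unique:
            raise ValueError("gene ids must be unique")
        if list(self.counts.columns) != list(self.design["sample_id"]):
            raise ValueError("count columns must match design sample_ids in order")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be nonnegative")
        bad_diet = set(self.design["diet"]) - set(DIET_LEVELS)
        bad_temp = set(self.design["temperature"]) - set(TEMPERATURE_LEVELS)
        if bad_diet or bad_temp:
            raise ValueError(f"unknown factor levels: {bad_diet | bad_temp}")

    @property
    def gene_ids(self):
        return list(self.counts.index)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


def make_design(
    n_per_group: int = 7,
    size_factor_range: tuple[float, float] = (0.7, 1.4),
    seed: int = 0,
) -> pd.DataFrame:
    """Balanced 2x2 sample sheet: ``n_per_group`` samples per (diet, temperature) cell.

    Size factors (library-size multipliers) are drawn uniformly from
    ``size_factor_range`` by a seeded generator.  The default of 7 replicates
    per cell matches a typical well-powered mouse cohort.
    """
    if n_per_group < 2:
        raise ValueError("insufficient replication: n_per_group must be >= 2")
    low, high = size_factor_range
    if low <= 0 or high < low:
        raise ValueError("size_factor_range must satisfy 0 < low <= high")
    rng = np.random.default_rng(seed)
    rows = []
    for diet in DIET_LEVELS:
        for temp in TEMPERATURE_LEVELS:
            for i in range(n_per_group):
                rows.append(
                    {
                        "sample_id": f"{diet}_{temp}_{i + 1}",
                        "diet": diet,
                        "temperature": temp,
                        "size_factor": float(rng.uniform(low, high)),
                    }
                )
    return pd.DataFrame(rows)


def plant_archetypes(
    n_genes_per_archetype: dict[str, int] | int = 200,
    effect_size: float = 1.5,
    baseline_log2_mean_range: tuple[float, float] = (3.0, 12.0),
    dispersion: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Ground-truth table: one row per gene with archetype and planted betas.

    ``n_genes_per_archetype`` may be a single count (applied to every
    archetype) or a mapping archetype -> count.  Sign of each gene's pattern
    is randomized.  Baselines (log2 mean counts) are uniform over
    ``baseline_log2_mean_range``; ``dispersion`` is the shared NB alpha
    (per-gene overrides are possible by editing the returned table).
    """
    if isinstance(n_genes_per_archetype, int):
        n_genes_per_archetype = {a: n_genes_per_archetype for a in ARCHETYPES}
    unknown = set(n_genes_per_archetype) - set(ARCHETYPES)
    if unknown:
        raise ValueError(f"unknown archetype: {sorted(unknown)}")
    if effect_size <= 0:
        raise ValueError("effect_size must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be nonnegative")
    lo, hi = baseline_log2_mean_range
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for arch in ARCHETYPES:
        n = int(n_genes_per_archetype.get(arch, 0))
        for _ in range(n):
            sign = 1 if rng.random() < 0.5 else -1
            bd, bt, bi = archetype_betas(arch, effect_size, sign)
            rows.append(
                {
                    "gene_id": f"g{idx:05d}",
                    "archetype": arch,
                    "beta0": float(rng.uniform(lo, hi)),
                    "beta_diet": bd,
                    "beta_temp": bt,
                    "beta_int": bi,
                    "dispersion": float(dispersion),
                }
            )
            idx += 1
    return pd.DataFrame(rows)


def simulate_counts(truth: pd.DataFrame, design: pd.DataFrame, seed: int = 0) -> CountMatrix:
    """Draw NB counts for every (gene, sample) from planted truth and design.

    The per-cell mean is ``sf_j * 2**(beta0 + x_d*b_diet + x_t*b_temp +
    x_d*x_t*b_int)``; variance is ``mu + alpha*mu**2``.  ``alpha = 0``
    degenerates to Poisson.  Fully reproducible from ``seed``.
    """
    if len(truth) == 0 or len(design) == 0:
        raise ValueError("truth and design must be non-empty")
    rng = np.random.default_rng(seed)
    x_d = (design["diet"] == "MetR").to_numpy(float)
    x_t = (design["temperature"] == "CE").to_numpy(float)
    sf = design.get("size_factor", pd.Series(np.ones(len(design)))).to_numpy(float)

    log2_mu = (
        truth["beta0"].to_numpy()[:, None]
        + np.outer(truth["beta_diet"], x_d)
        + np.outer(truth["beta_temp"], x_t)
        + np.outer(truth["beta_int"], x_d * x_t)
    )
    mu = sf[None, :] * np.exp2(log2_mu)
    alpha = truth["dispersion"].to_numpy()[:, None]

    counts = np.empty_like(mu, dtype=np.int64)
    pois = alpha[:, 0] <= 0
    if pois.any():
        counts[pois] = rng.poisson(mu[pois])
    if (~pois).any():
        a = alpha[~pois]
        m = mu[~pois]
        # NB as gamma-Poisson mixture; n = 1/alpha, p = n / (n + mu)
        n_param = 1.0 / a
        counts[~pois] = rng.negative_binomial(n_param, n_param / (n_param + m))
    cm = pd.DataFrame(counts, index=truth["gene_id"].to_numpy(), columns=design["sample_id"].to_numpy())
    return CountMatrix(counts=cm, design=design.reset_index(drop=True), truth=truth)


def noise_free_de_table(truth: pd.DataFrame) -> pd.DataFrame:
    """Idealized DE table from exact planted effects (the classifier oracle input).

    Each gene's four contrast log2 fold changes are the closed-form sums of
    its planted betas; p-values are 0 so that direction calls are decided by
    the magnitude threshold alone.  Used to verify that every archetype's
    exact effect pattern lands in its intended regulation category.
    """
    rows = []
    for rec in truth.itertuples(index=False):
        l2 = {
            "A": rec.beta_temp,
            "B": rec.beta_diet,
            "AB": rec.beta_temp + rec.beta_diet + rec.beta_int,
            "INT": rec.beta_int,
        }
        for contrast, fc in l2.items():
            rows.append(
                {
                    "gene_id": rec.gene_id,
                    "contrast": contrast,
                    "log2fc": float(fc),
                    "se": 0.0,
                    "wald": 0.0,
                    "pvalue": 0.0,
                    "padj": 0.0,
                }
            )
    return pd.DataFrame(rows)
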