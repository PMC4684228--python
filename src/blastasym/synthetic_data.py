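"""Synthetic 8-blastomere embryos with known ground truth.

The generator emulates the design of a single-blastomere RNA-seq screen of
early cleavage-stage embryos: each embryo contributes eight blastomeres
carrying the full 2x2x2 labeling of the animal-vegetal, dorsal-ventral and
left-right axes; library sizes are log-normal around a 25-million-read
standard; counts are NB2 with gene-specific dispersion.  A configurable
fraction of genes is truly asymmetric on the animal-vegetal axis, split
between the poles, with vegetal log-folds drawn from a heavier-tailed
distribution than animal log-folds (mean folds ~4.2 and ~1.5 respectively,
the vegetal tail reaching >100-fold); no dorsal-ventral or left-right
effects exist by default.

Fold-changes are applied symmetrically about the baseline (x sqrt(f) on the
enriched side, / sqrt(f) on the other) so the baseline is the geometric mean
across poles and baseline and fold stay separately identifiable.  Baselines
are drawn log-normal and rescaled to sum to the standard library, so that
recomputed library sizes track the drawn ones and normalized counts sit on
the baseline scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .count_core import POLES, STANDARD_LIBRARY, validate_counts, validate_meta

__all__ = [
    "SimConfig",
    "draw_truth",
    "simulate",
    "simulate_from_truth",
    "simulate_annotations",
    "make_xref_fixture",
]

TRUTH_COLUMNS = [
    "gene_id", "is_asymmetric", "axis", "enriched_pole",
    "true_fold", "true_alpha", "true_baseline",
]


@dataclass
class SimConfig:
    """Study conditions for a synthetic blastomere experiment.

    Log-folds of asymmetric genes are Gamma distributed (shape derived from
    the target mean fold through the Gamma MGF, ``E[f] = (1-scale)^-shape``),
    giving an exponential-tailed fold distribution whose vegetal tail
    reaches the >100-fold range while the animal folds stay below ~4.
    Dispersions are log-normal with median 0.02 — small enough that pooled
    tests can resolve folds close to 1.1, matching the detection floor of
    deeply sequenced blastomere libraries.
    """

    n_embryos: int = 4
    n_genes: int = 2000
    frac_asymmetric_av: float = 0.07
    vegetal_share: float = 448 / 908
    frac_asymmetric_dv: float = 0.0
    frac_asymmetric_lr: float = 0.0
    vegetal_fold_mean: float = 4.2
    vegetal_fold_tail: float = 0.75   # Gamma scale of vegetal log-folds
    animal_fold_mean: float = 1.5
    animal_fold_tail: float = 0.30    # Gamma scale of animal log-folds
    baseline_sdlog: float = 2.0       # dynamic range of expression levels
    alpha_median: float = 0.02
    alpha_sdlog: float = 1.0
    library_size_mean: float = float(STANDARD_LIBRARY)
    library_size_cv: float = 0.3
    seed: int | None = None

    def __post_init__(self):
        for name in ("frac_asymmetric_av", "frac_asymmetric_dv",
                     "frac_asymmetric_lr", "vegetal_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_asymmetric_av + self.frac_asymmetric_dv + self.frac_asymmetric_lr > 1:
            raise ValueError("asymmetric fractions sum past 1")
        for name in ("vegetal_fold_mean", "animal_fold_mean", "alpha_median",
                     "library_size_mean", "library_size_cv", "baseline_sdlog",
                     "vegetal_fold_tail", "animal_fold_tail", "alpha_sdlog"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.vegetal_fold_tail < 1 and 0 < self.animal_fold_tail < 1):
            raise ValueError("fold tail scales must lie in (0, 1) for finite mean folds")

    def to_dict(self) -> dict:
        return asdict(self)


def _fold_shape(mean_fold: float, scale: float) -> float:
    # Gamma MGF at 1: E[exp(L)] = (1 - scale)^(-shape)
    return math.log(mean_fold) / (-math.log1p(-scale))


def _make_meta(n_embryos: int) -> pd.DataFrame:
    rows = []
    for e in range(1, n_embryos + 1):
        for av in POLES["av"]:
            for dv in POLES["dv"]:
                for lr in POLES["lr"]:
                    sid = f"E{e}-{av[0].upper()}{dv[0].upper()}{lr[0].upper()}"
                    rows.append({"sample_id": sid, "embryo_id": f"E{e}",
                                 "av": av, "dv": dv, "lr": lr})
    return pd.DataFrame(rows).set_index("sample_id")


def draw_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the per-gene ground truth implied by the configuration."""
    g = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(g)]

    baseline = rng.lognormal(mean=0.0, sigma=config.baseline_sdlog, size=g)
    baseline *= STANDARD_LIBRARY / baseline.sum()
    alpha = rng.lognormal(mean=math.log(config.alpha_median),
                          sigma=config.alpha_sdlog, size=g)

    u = rng.random(g)
    axis = np.full(g, "", dtype=object)
    edges = np.cumsum([config.frac_asymmetric_av, config.frac_asymmetric_dv,
                       config.frac_asymmetric_lr])
    axis[u < edges[0]] = "av"
    axis[(u >= edges[0]) & (u < edges[1])] = "dv"
    axis[(u >= edges[1]) & (u < edges[2])] = "lr"

    pole = np.full(g, "", dtype=object)
    fold = np.ones(g)
    veg_shape = _fold_shape(config.vegetal_fold_mean, config.vegetal_fold_tail)
    anim_shape = _fold_shape(config.animal_fold_mean, config.animal_fold_tail)
    for i in np.flatnonzero(axis != ""):
        ax = axis[i]
        if ax == "av":
            if rng.random() < config.vegetal_share:
                pole[i] = "vegetal"
                logf = rng.gamma(veg_shape, config.vegetal_fold_tail)
            else:
                pole[i] = "animal"
                logf = rng.gamma(anim_shape, config.animal_fold_tail)
        else:
            pole[i] = POLES[ax][int(rng.random() < 0.5)]
            logf = rng.gamma(anim_shape, config.animal_fold_tail)
        fold[i] = math.exp(logf)

    return pd.DataFrame({
        "gene_id": gene_ids,
        "is_asymmetric": axis != "",
        "axis": axis,
        "enriched_pole": pole,
        "true_fold": fold,
        "true_alpha": alpha,
        "true_baseline": baseline,
    })


def simulate_from_truth(
    truth: pd.DataFrame, config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (counts, meta, truth) from an explicit truth table."""
    if rng is None:
        if config.seed is None:
            raise ValueError("a seed is required")
        rng = np.random.default_rng(config.seed)
    meta = _make_meta(config.n_embryos)
    n = len(meta)
    g = len(truth)

    sigma = math.sqrt(math.log1p(config.library_size_cv ** 2))
    sizes = rng.lognormal(math.log(config.library_size_mean) - sigma ** 2 / 2, sigma, n)

    # mean matrix: baseline x sqrt-fold split on the gene's axis
    mu = np.outer(truth["true_baseline"].to_numpy(), sizes / STANDARD_LIBRARY)
    for ax in POLES:
        on_axis = (truth["axis"] == ax).to_numpy()
        if not on_axis.any():
            continue
        enriched_side2 = (truth["enriched_pole"] == POLES[ax][1]).to_numpy()
        sample_side2 = (meta[ax] == POLES[ax][1]).to_numpy()
        sqrtf = np.sqrt(truth["true_fold"].to_numpy())
        up = np.where(enriched_side2[:, None], sample_side2[None, :], ~sample_side2[None, :])
        factor = np.where(up, sqrtf[:, None], 1.0 / sqrtf[:, None])
        mu = np.where(on_axis[:, None], mu * factor, mu)

    alpha = truth["true_alpha"].to_numpy()[:, None]
    counts = np.empty((g, n), dtype=np.int64)
    pois = (alpha <= 0).ravel()
    if pois.any():
        counts[pois] = rng.poisson(mu[pois])
    if (~pois).any():
        k = 1.0 / alpha[~pois]
        lam = rng.gamma(shape=np.broadcast_to(k, mu[~pois].shape),
                        scale=mu[~pois] / k)
        counts[~pois] = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=pd.Index(truth["gene_id"], name="gene_id"),
                             columns=meta.index)
    validate_counts(counts_df)
    validate_meta(meta, counts=counts_df)
    return counts_df, meta, truth.reset_index(drop=True)


def simulate(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a full synthetic experiment: counts, metadata, truth table."""
    if config.seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(config.seed)
    truth = draw_truth(config, rng)
    return simulate_from_truth(truth, config, rng)


def simulate_annotations(
    truth: pd.DataFrame,
    universe,
    base_rate: float = 0.3,
    animal_enrichment_factor: float = 2.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Bernoulli disease-annotation flags, elevated for animal-enriched genes."""
    if seed is None:
        raise ValueError("a seed is required")
    if not 0.0 <= base_rate <= 1.0 or animal_enrichment_factor < 0:
        raise ValueError("invalid annotation rates")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    animal = set(truth.loc[truth["enriched_pole"] == "animal", "gene_id"])
    rate = np.where(
        [g in animal for g in universe],
        min(1.0, base_rate * animal_enrichment_factor),
        base_rate,
    )
    flags = (rng.random(len(universe)) < rate).astype(int)
    return pd.DataFrame({"gene_id": universe, "disease_flag": flags})


def make_xref_fixture(
    n_probes: int, noise_rate: float, seed: int | None = None
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.Series]:
    """Planted probe -> transcript mapping with majority-true vote structure.

    Every probe gets three true routes (direct, via one EST cluster, and via
    that cluster's paired mate); with probability ``noise_rate`` a probe
    additionally gets two noisy direct hits onto a wrong transcript plus two
    extra true routes, so noise votes stay a strict minority.  Returns the
    hit tables, the pair-link table and the planted truth mapping.
    """
    if not 0.0 <= noise_rate < 0.5:
        raise ValueError("noise_rate must lie in [0, 0.5)")
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)

    def hit(q, t):
        return {"query_id": q, "target_id": t, "percent_identity": 97.5,
                "e_value": 1e-40, "bit_score": 200.0}

    direct, p2c, c2r, pairs, truth = [], [], [], [], {}
    for i in range(n_probes):
        probe, ref = f"probe{i:04d}", f"ref{i:04d}"
        c1, c2 = f"clu{i:04d}a", f"clu{i:04d}b"
        truth[probe] = ref
        direct.append(hit(probe, ref))
        p2c.append(hit(probe, c1))
        c2r.append(hit(c1, ref))
        pairs.append({"cluster_a": c1, "cluster_b": c2})
        c2r.append(hit(c2, ref))
        if rng.random() < noise_rate:
            wrong = f"ref{(i + 1 + int(rng.integers(n_probes - 1))) % n_probes:04d}"
            direct.append(hit(probe, wrong))
            direct.append(hit(probe + "_alt", wrong))  # decoy query, ignored
            p2c.append(hit(probe, c2))                 # extra vote via mate pair
    tables = {
        "direct": pd.DataFrame(direct),
        "probe_to_cluster": pd.DataFrame(p2c),
        "cluster_to_ref": pd.DataFrame(c2r),
    }
    return tables, pd.DataFrame(pairs), pd.Series(truth, name="target_id")
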