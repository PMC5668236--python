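"""Synthetic microbiome-phenotype cohorts with known ground truth.

Emulates the structure of a 240-animal 16S study: zero-inflated log-normal
OTU abundances rendered to counts at a fixed library depth, two sexes with a
pen/batch structure, serum traits with planted presence- and abundance-driven
microbial effects plus covariate effects, and Greengenes-style taxonomy
strings spanning the dominant gut phyla. The generator records every planted
effect and the realised microbiome-explained variance so each downstream
stage can be tested against a known answer.

Effect-size magnitudes are heavy-tailed (lognormal): in real cohorts of this
size a handful of taxa dominate the association signal, and a flat effect
profile would make every planted feature individually undetectable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import (Lineage, OtuTable, PhenotypeTable, TaxonomyMap,
                     ValidationError, write_feature_table)

__all__ = [
    "SimulationConfig",
    "CausalFeature",
    "SimulationTruth",
    "simulate_community",
    "simulate_traits",
    "simulate_taxonomy",
    "generate_dataset",
    "TRAIT_BASELINES",
]

# cohort trait means and SDs (mmol/L) used as generator baselines
TRAIT_BASELINES = {
    "GLU": (3.05, 1.86),
    "TCHOL": (2.21, 0.36),
    "TG": (0.22, 0.12),
    "HDL": (1.19, 0.41),
    "LDL": (1.48, 0.31),
}

# boar-minus-gilt shifts planted by default (LDL only; the derived LDL/HDL
# and AI indices inherit a sex contrast through LDL and HDL automatically)
DEFAULT_SEX_EFFECTS = {"LDL": 0.17}

PHYLUM_WEIGHTS = {
    "Firmicutes": 0.52,
    "Bacteroidetes": 0.30,
    "Spirochaetes": 0.07,
    "Proteobacteria": 0.06,
    "Fusobacteria": 0.05,
}

# phylum -> (class, order, [(family, [genera, "" = unassigned]), ...])
_TAXA_POOLS = {
    "Firmicutes": ("Clostridia", "Clostridiales", [
        ("Lachnospiraceae", ["Blautia", "Roseburia", "Coprococcus", ""]),
        ("Ruminococcaceae", ["Ruminococcus", "Faecalibacterium", ""]),
        ("Veillonellaceae", ["Megasphaera", "Dialister", ""]),
    ]),
    "Bacteroidetes": ("Bacteroidia", "Bacteroidales", [
        ("Bacteroidaceae", ["Bacteroides"]),
        ("Prevotellaceae", ["Prevotella", ""]),
        ("Paraprevotellaceae", ["Paraprevotella", ""]),
    ]),
    "Spirochaetes": ("Spirochaetia", "Spirochaetales", [
        ("Spirochaetaceae", ["Treponema", ""]),
    ]),
    "Proteobacteria": ("Gammaproteobacteria", "Enterobacteriales", [
        ("Enterobacteriaceae", ["Escherichia", ""]),
    ]),
    "Fusobacteria": ("Fusobacteriia", "Fusobacteriales", [
        ("Fusobacteriaceae", ["Fusobacterium", ""]),
    ]),
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Defaults reproduce the study conditions this generator emulates: 240
    samples (113 castrated boars / 127 gilts), 10,000-tag libraries, feature
    prevalence uniform on (0.2, 1], and 30 causal features split evenly
    across presence-driven, abundance-driven and both-driven effects on one
    target trait.
    """

    n_samples: int = 240
    n_features: int = 500
    boar_fraction: float = 113 / 240
    n_batches: int = 6
    batch_sd: float = 0.15           # batch effect SD, in trait-SD units
    prevalence_range: tuple = (0.2, 1.0)
    log_mean_sd: float = 1.5         # spread of per-feature log abundance means
    log_sd_range: tuple = (0.5, 1.5)  # per-feature log abundance SDs
    depth: int = 10_000
    n_binary_effects: int = 10
    n_quant_effects: int = 10
    n_both_effects: int = 10
    effect_scale: float = 0.5        # strongest effect, in trait-SD units
    effect_decay: float = 0.35       # geometric decay of effect magnitudes
    causal_min_abund: float = 5e-4   # causal features must pass this mean
                                     # relative abundance (the analysis filter)
    causal_trait: str = "GLU"
    target_r2: float | None = None   # realised Var(microbial)/Var(trait)
    sex_effects: dict = field(default_factory=lambda: dict(DEFAULT_SEX_EFFECTS))
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.prevalence_range[0] <= self.prevalence_range[1] <= 1:
            raise ValidationError("prevalence_range must lie within (0, 1]")
        n_causal = (self.n_binary_effects + self.n_quant_effects
                    + self.n_both_effects)
        if n_causal > self.n_features:
            raise ValidationError("more causal features than features")
        if self.target_r2 is not None and not 0.0 <= self.target_r2 < 1.0:
            raise ValidationError("target_r2 must lie in [0, 1)")
        if self.depth < 1:
            raise ValidationError("library depth must be >= 1")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator stage."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class CausalFeature:
    feature_id: str
    effect_type: str          # binary | quant | both
    beta1: float              # trait shift per presence (0 unless binary/both)
    beta2: float              # trait shift per SD of log10 abundance


@dataclass
class SimulationTruth:
    """Everything needed to check the pipeline against the generator."""

    causal_trait: str
    causal_features: list
    realized_r2: float
    target_r2: float | None
    sex_effects: dict
    batch_effects: dict
    noise_sd: dict
    seed: int

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["causal_features"] = [CausalFeature(**c)
                                      for c in payload["causal_features"]]
        return cls(**payload)


def simulate_community(config: SimulationConfig, seed=None) -> OtuTable:
    """Zero-inflated log-normal community rendered to counts.

    Presence ~ Bernoulli(per-feature prevalence); abundances of present
    features are log-normal, closed to proportions per sample and drawn as a
    multinomial of ``depth`` tags, so every column sums exactly to depth.
    """
    rng = np.random.default_rng(seed) if seed is not None else config.rng(0)
    F, n = config.n_features, config.n_samples
    lo, hi = config.prevalence_range
    prevalence = rng.uniform(lo, hi, size=F)
    log_mean = rng.normal(0.0, config.log_mean_sd, size=F)
    log_sd = rng.uniform(*config.log_sd_range, size=F)

    present = rng.random((F, n)) < prevalence[:, None]
    empty = ~present.any(axis=0)
    if empty.any():  # vanishingly rare at default sizes; keep columns valid
        present[rng.integers(0, F, size=int(empty.sum())), empty] = True
    abund = np.where(
        present,
        np.exp(log_mean[:, None] + log_sd[:, None] * rng.normal(size=(F, n))),
        0.0,
    )
    probs = abund / abund.sum(axis=0)
    counts = np.empty((F, n), dtype=np.int64)
    for j in range(n):
        counts[:, j] = rng.multinomial(config.depth, probs[:, j])
    feature_ids = [f"OTU{i + 1:04d}" for i in range(F)]
    sample_ids = [f"S{j + 1:04d}" for j in range(n)]
    return OtuTable(pd.DataFrame(counts, index=feature_ids, columns=sample_ids),
                    kind="counts")


def _standardized_log10(rel_row: np.ndarray) -> np.ndarray:
    """z-scored log10 abundance among present samples; absent -> 0."""
    out = np.zeros_like(rel_row)
    mask = rel_row > 0
    if mask.sum() >= 2:
        la = np.log10(rel_row[mask])
        sd = la.std(ddof=1)
        if sd > 0:
            out[mask] = (la - la.mean()) / sd
    return out


def _scale_for_target_r2(core: np.ndarray, rest: np.ndarray,
                         target: float) -> float:
    """Scale s such that Var(s*core) / Var(s*core + rest) == target exactly
    on this cohort (solves the resulting quadratic in s)."""
    a = float(np.var(core))
    if a == 0.0:
        if target == 0.0:
            return 0.0
        raise ValidationError("target_r2 > 0 requires causal features with "
                              "non-degenerate abundance patterns")
    b = float(np.var(rest))
    c = float(np.cov(core, rest, ddof=0)[0, 1])
    # s^2 a (1 - t) - 2 t c s - t b = 0
    disc = target**2 * c**2 + a * (1 - target) * target * b
    s = (target * c + np.sqrt(disc)) / (a * (1 - target))
    if s < 0:
        raise ValidationError("unsatisfiable target_r2 for this configuration")
    return float(s)


def _pick_causal(rng, prevalence: np.ndarray, abund_ok: np.ndarray,
                 config: SimulationConfig):
    """Causal indices per effect type, drawn where the effect is in
    principle identifiable: mid prevalence for presence effects, enough
    present samples for abundance effects, and abundance above the analysis
    filter (a planted effect on a feature the pipeline discards would make
    the generator's truth unrecoverable by construction)."""
    n_feat = len(prevalence)
    idx = np.arange(n_feat)
    pools = {
        "binary": idx[(prevalence >= 0.25) & (prevalence <= 0.9) & abund_ok],
        "quant": idx[(prevalence >= 0.5) & abund_ok],
        "both": idx[(prevalence >= 0.4) & (prevalence <= 0.9) & abund_ok],
    }
    wanted = {"binary": config.n_binary_effects,
              "quant": config.n_quant_effects,
              "both": config.n_both_effects}
    chosen: dict[str, np.ndarray] = {}
    used: set[int] = set()
    for kind in ("both", "binary", "quant"):
        pool = np.array([i for i in pools[kind] if i not in used])
        if len(pool) < wanted[kind]:
            raise ValidationError(
                f"not enough eligible features for {kind} effects")
        pick = rng.choice(pool, size=wanted[kind], replace=False)
        used.update(int(i) for i in pick)
        chosen[kind] = np.sort(pick)
    return chosen


def simulate_traits(table: OtuTable, config: SimulationConfig,
                    seed=None) -> tuple[PhenotypeTable, SimulationTruth]:
    """Generate all seven serum traits for a simulated community.

    The causal trait receives planted microbial effects of the form
    beta1*presence + beta2*(standardised log10 abundance among present
    samples). Effect magnitudes follow a geometric ladder
    (``effect_scale * effect_decay**rank`` in variance-normalised predictor
    units, ranks interleaved across the both/binary/quant types with random
    signs): a handful of taxa dominating the association signal is the
    profile real cohorts of this size show. The residual noise is made
    empirically orthogonal to the planted predictors, and with ``target_r2``
    set the whole microbial part is rescaled, so the stated per-feature
    effects and the overall variance ratio are realised exactly on the
    generated cohort rather than only in expectation. HDL is generated on
    the log scale and is therefore positive by construction; LDL/HDL and AI
    are derived from their defining identities.
    """
    rng = np.random.default_rng(seed) if seed is not None else config.rng(1)
    n = table.n_samples
    if n != config.n_samples:
        raise ValidationError("table does not match config.n_samples")

    n_boars = int(round(config.boar_fraction * n))
    sex = np.array(["castrated_boar"] * n_boars + ["gilt"] * (n - n_boars))
    rng.shuffle(sex)
    batch_levels = [f"pen{b + 1}" for b in range(config.n_batches)]
    batch = np.array([batch_levels[i % config.n_batches] for i in range(n)])
    rng.shuffle(batch)
    is_boar = (sex == "castrated_boar").astype(float)

    rel = table.relative_abundance().values
    prevalence = (rel > 0).mean(axis=1)
    abund_ok = rel.mean(axis=1) >= config.causal_min_abund
    chosen = _pick_causal(rng, prevalence, abund_ok, config)

    sd_causal = TRAIT_BASELINES[config.causal_trait][1] \
        if config.causal_trait in TRAIT_BASELINES else 1.0

    # rank k across interleaved types -> magnitude effect_scale * decay^k
    ladder: list[tuple[str, int]] = []
    counts = {"both": config.n_both_effects, "binary": config.n_binary_effects,
              "quant": config.n_quant_effects}
    pos = {k: 0 for k in counts}
    while any(pos[k] < counts[k] for k in counts):
        for kind in ("quant", "binary", "both"):
            if pos[kind] < counts[kind]:
                ladder.append((kind, chosen[kind][pos[kind]]))
                pos[kind] += 1

    causal: list[CausalFeature] = []
    core = np.zeros(n)
    predictors = []
    for rank, (kind, i) in enumerate(ladder):
        fid = table.feature_ids[i]
        lam = config.effect_scale * sd_causal * config.effect_decay**rank
        sign = float(rng.choice([-1.0, 1.0]))
        row = rel[i]
        b = (row > 0).astype(float)
        q = _standardized_log10(row)
        sd_b, sd_q = b.std(), q.std()
        if kind == "binary":
            beta1, beta2 = lam * sign / sd_b, 0.0
        elif kind == "quant":
            beta1, beta2 = 0.0, lam * sign / sd_q
        else:  # both: split the contribution evenly across the two parts
            w = lam * sign / np.sqrt(2.0)
            beta1, beta2 = w / sd_b, w / sd_q
        contrib = beta1 * b + beta2 * q
        causal.append(CausalFeature(fid, kind, float(beta1), float(beta2)))
        predictors.append(contrib - contrib.mean())
        core += contrib

    frame = {"sample_id": [f for f in table.sample_ids], "sex": sex,
             "batch": batch}
    batch_effects: dict[str, dict] = {}
    noise_sd: dict[str, float] = {}
    realized_r2 = 0.0

    for trait, (mean, sd) in TRAIT_BASELINES.items():
        beff = {lev: float(rng.normal(0.0, config.batch_sd * sd))
                for lev in batch_levels}
        batch_effects[trait] = beff
        cov_part = np.array([beff[b] for b in batch])
        cov_part += config.sex_effects.get(trait, 0.0) * is_boar
        noise = rng.normal(0.0, sd, size=n)
        noise_sd[trait] = sd
        if trait == config.causal_trait:
            if predictors:
                # noise orthogonal to the planted predictors: the stated
                # effect sizes are then exact in this cohort, not merely
                # their expectation
                P = np.column_stack(predictors)
                coef, *_ = np.linalg.lstsq(P, noise - noise.mean(), rcond=None)
                noise = noise - P @ coef
                noise *= sd / noise.std()
            s = 1.0
            if config.target_r2 is not None:
                s = _scale_for_target_r2(core, cov_part + noise,
                                         config.target_r2)
            micro = s * core
            values = mean + micro + cov_part + noise
            tot = np.var(values)
            realized_r2 = float(np.var(micro) / tot) if tot > 0 else 0.0
            for cf in causal:
                cf.beta1 *= s
                cf.beta2 *= s
        else:
            values = mean + cov_part + noise
        if trait == "HDL":
            # lognormal moment match keeps HDL strictly positive
            cv2 = (sd / mean) ** 2
            sig = np.sqrt(np.log1p(cv2))
            z = (values - mean) / sd  # reuse the same shocks on the log scale
            values = np.exp(np.log(mean) - 0.5 * sig**2 + sig * z)
        frame[trait] = values

    pheno = PhenotypeTable(pd.DataFrame(frame)).derive_lipid_indices()
    truth = SimulationTruth(
        causal_trait=config.causal_trait,
        causal_features=causal,
        realized_r2=realized_r2,
        target_r2=config.target_r2,
        sex_effects=dict(config.sex_effects),
        batch_effects=batch_effects,
        noise_sd=noise_sd,
        seed=config.seed,
    )
    return pheno, truth


def simulate_taxonomy(feature_ids, seed=None,
                      config: SimulationConfig | None = None) -> TaxonomyMap:
    """Synthetic Greengenes-style lineages over the dominant gut phyla."""
    if seed is None and config is not None:
        rng = config.rng(2)
    else:
        rng = np.random.default_rng(seed)
    phyla = list(PHYLUM_WEIGHTS)
    weights = np.array([PHYLUM_WEIGHTS[p] for p in phyla])
    weights = weights / weights.sum()
    mapping = {}
    for fid in feature_ids:
        phylum = phyla[rng.choice(len(phyla), p=weights)]
        cls, order, families = _TAXA_POOLS[phylum]
        family, genera = families[rng.integers(len(families))]
        genus = genera[rng.integers(len(genera))]
        lineage = (f"k__Bacteria;p__{phylum};c__{cls};o__{order};"
                   f"f__{family};g__{genus}")
        mapping[fid] = Lineage.from_string(lineage)
    return TaxonomyMap(mapping)


def generate_dataset(config: SimulationConfig, outdir) -> dict:
    """Write a complete synthetic dataset (feature table, taxonomy,
    phenotypes, ground-truth sidecar) that loads back through the readers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = simulate_community(config)
    pheno, truth = simulate_traits(table, config)
    taxonomy = simulate_taxonomy(table.feature_ids, config=config)
    paths = {
        "feature_table": outdir / "feature_table.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "phenotypes": outdir / "phenotypes.csv",
        "truth": outdir / "truth.json",
    }
    write_feature_table(table, paths["feature_table"])
    taxonomy.write_tsv(paths["taxonomy"])
    pheno.write(paths["phenotypes"])
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
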