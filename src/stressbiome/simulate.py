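"""Synthetic two-cohort pregnancy-study generator.

Emulates the statistical structure the downstream analyses assume: an
urban (n=38) and a suburban (n=46) cohort sampled at two trimesters
(T2/T3), PSS-10 Likert responses driven by two correlated latent factors
(Emotional Distress and Self-Efficacy) with cohort-specific measurement
non-invariance planted on a configurable item subset, zero-inflated
compositional ASV counts with genus-level covariance and planted
taxon-trait effects, and a log-normal 21-analyte cytokine panel with one
anti-correlated analyte (CXCL11-like) optionally coupled to a planted
taxon.

Every generated table carries its generating parameters in
``SyntheticStudy.truth`` so downstream estimators can be checked for
planted-truth recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

ITEMS = list("abcdefghij")
ED_ITEMS = ["a", "b", "c", "f", "i", "j"]
SE_ITEMS = ["d", "e", "g", "h"]

CYTOKINES = [
    "CX3CL1", "GM-CSF", "IFNg", "IL-1b", "IL-2", "IL-4", "IL-5", "IL-6",
    "IL-7", "IL-8", "IL-10", "IL-12p70", "IL-13", "IL-17A", "IL-21",
    "IL-23", "CXCL11", "CCL3", "CCL4", "CCL20", "TNFa",
]

# Likert discretization cut points on the standardized latent response;
# chosen so all five categories are occupied at cohort sizes near 40.
LIKERT_THRESHOLDS = (-1.5, -0.5, 0.5, 1.5)

#: Site-conditional covariate distributions. Race frequencies, obesity and
#: nulliparity rates, age and BMI moments follow the two cohorts' printed
#: demographic summaries (urban: younger, higher BMI, majority women of
#: color; suburban: majority non-Hispanic White).
COVARIATE_PROFILES = {
    "urban": {
        "race_levels": ["Hispanic", "NH_Black", "NH_White"],
        "race_probs": [12 / 39, 24 / 39, 3 / 39],
        "obese_rate": 17 / 38,          # 44.7%
        "nulliparous_rate": 12 / 38,    # 31.6%
        "age_mean": 28.6, "age_sd": 5.5,
        "bmi_mean": 32.0, "bmi_sd": 8.2,
        "t2_weeks_mean": 24.0,
    },
    "suburban": {
        "race_levels": ["Hispanic", "NH_Black", "NH_White"],
        "race_probs": [1 / 42, 5 / 42, 36 / 42],
        "obese_rate": 13 / 46,          # 28.3%
        "nulliparous_rate": 19 / 46,    # 41.3%
        "age_mean": 32.3, "age_sd": 3.0,
        "bmi_mean": 28.9, "bmi_sd": 6.0,
        "t2_weeks_mean": 29.0,
    },
}


@dataclass
class StudyConfig:
    """Generating parameters for one synthetic two-cohort study.

    Defaults are the study conditions: cohort sizes 38/46, ten Likert
    items with the canonical ED/SE assignment, non-invariance planted on
    items {e, f, h} (loading and intercept shifted in the suburban
    cohort), a latent ED-SE correlation of -0.4, and a single planted
    negative Self-Efficacy effect on a *Bacteroides uniformis*-like ASV
    that is also coupled to the CXCL11-like analyte.
    """

    n_urban: int = 38
    n_suburban: int = 46
    n_items: int = 10
    item_factor_map: dict = field(
        default_factory=lambda: {i: ("ED" if i in ED_ITEMS else "SE") for i in ITEMS}
    )
    noninvariant_items: frozenset = frozenset({"e", "f", "h"})
    base_loading: float = 0.8
    noninvariant_loading_gap: float = 0.5
    noninvariant_intercept_gap: float = 0.3
    factor_corr: float = -0.4
    latent_visit_corr: float = 0.7
    n_asv: int = 150
    n_genera: int = 40
    n_cytokines: int = 21
    depth_range: tuple = (8000, 30000)
    planted_effects: tuple = (("B_uniformis_like", "SE", -1, 1.0),)
    cytokine_coupling: tuple = (("CXCL11", "B_uniformis_like", -0.4),)
    cxcl11_loading: float = -0.6
    cytokine_loading: float = 0.6
    cytokine_bmi_beta: float = 0.03
    abundance_icc: float = 0.5
    dropout_a: float = 4.0
    dropout_b: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        if self.n_urban <= 0 or self.n_suburban <= 0:
            raise ValueError("cohort sizes must be positive")
        if set(self.item_factor_map) != set(ITEMS[: self.n_items]):
            raise ValueError("item_factor_map must cover exactly the study items")
        if any(f not in ("ED", "SE") for f in self.item_factor_map.values()):
            raise ValueError("each item must map to ED or SE")
        if not abs(self.factor_corr) < 1:
            raise ValueError("|factor_corr| must be < 1")
        if self.depth_range[0] < 1000:
            raise ValueError("minimum sequencing depth must be >= 1000")
        if self.n_cytokines != len(CYTOKINES):
            raise ValueError(f"cytokine panel is fixed at {len(CYTOKINES)} analytes")


@dataclass
class SyntheticStudy:
    """Container for one generated study plus its generating truth."""

    metadata: pd.DataFrame
    likert: pd.DataFrame
    factors: pd.DataFrame
    asv_counts: pd.DataFrame
    taxonomy: pd.DataFrame
    cytokines: pd.DataFrame
    truth: dict


def _loading_matrices(config: StudyConfig) -> dict:
    """Per-cohort item loading/intercept vectors; suburban carries the gap.

    Gap directions alternate within each factor (first non-invariant item
    of a factor shifts down, the next up, ...). A common-direction shift
    of half a factor's items is absorbed by the group's free factor
    variance/mean and leaves the non-invariant set unidentifiable;
    alternating directions keep the planted truth recoverable.
    """
    fmap = config.item_factor_map
    sign_of = {}
    for factor in ("ED", "SE"):
        k = 0
        for item in sorted(config.noninvariant_items):
            if fmap.get(item) == factor:
                sign_of[item] = -1 if k % 2 == 0 else 1
                k += 1
    lam = {}
    for cohort in ("urban", "suburban"):
        lam_c = np.full(config.n_items, config.base_loading)
        nu_c = np.zeros(config.n_items)
        if cohort == "suburban":
            for j, item in enumerate(ITEMS[: config.n_items]):
                if item in config.noninvariant_items:
                    s = sign_of[item]
                    lam_c[j] += s * config.noninvariant_loading_gap
                    nu_c[j] -= s * config.noninvariant_intercept_gap
        lam[cohort] = (lam_c, nu_c)
    return lam


def generate_covariates(config: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sample-level metadata: one row per participant-visit (T2 and T3).

    Participant-level covariates (site, race/ethnicity, age, BMI, parity,
    obesity) are drawn from site-conditional distributions and repeated on
    both visit rows; gestational weeks advance between visits.
    """
    config.validate()
    rows = []
    pid = 0
    for site, n in (("urban", config.n_urban), ("suburban", config.n_suburban)):
        prof = COVARIATE_PROFILES[site]
        for _ in range(n):
            pid += 1
            race = prof["race_levels"][rng.choice(3, p=prof["race_probs"])]
            age = float(np.clip(rng.normal(prof["age_mean"], prof["age_sd"]), 18, 45))
            bmi = float(np.clip(rng.normal(prof["bmi_mean"], prof["bmi_sd"]), 16, 60))
            obese = bool(rng.random() < prof["obese_rate"])
            nullip = bool(rng.random() < prof["nulliparous_rate"])
            w2 = float(np.clip(rng.normal(prof["t2_weeks_mean"], 1.5), 14, 28))
            w3 = w2 + float(np.clip(rng.normal(9.0, 1.5), 2, None))
            for tri, weeks in (("T2", w2), ("T3", min(w3, 41.0))):
                rows.append(
                    dict(
                        participant=f"P{pid:04d}",
                        site=site,
                        race=race,
                        age=round(age, 1),
                        bmi=round(bmi, 1),
                        obese=obese,
                        nulliparous=nullip,
                        trimester=tri,
                        gestational_weeks=round(weeks, 1),
                    )
                )
    meta = pd.DataFrame(rows)
    meta.index = meta["participant"] + "_" + meta["trimester"]
    meta.index.name = "sample"
    return meta


def generate_latent_and_likert(
    config: StudyConfig, metadata: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latent (ED, SE) factors and thresholded five-category item responses.

    Latent scores are bivariate normal with correlation ``factor_corr`` at
    the participant level, wobbling between visits with correlation
    ``latent_visit_corr``. Item response = loading * factor + intercept +
    unit-normal noise, standardized by the base-model response scale and
    cut at fixed thresholds into categories 0-4. Items listed in
    ``noninvariant_items`` use cohort-shifted loadings/intercepts.

    Returns (likert, factors); both indexed like ``metadata``.
    """
    lam = _loading_matrices(config)
    n_items = config.n_items
    cov = np.array([[1.0, config.factor_corr], [config.factor_corr, 1.0]])
    chol = np.linalg.cholesky(cov)

    participants = metadata["participant"].unique()
    base = {p: chol @ rng.standard_normal(2) for p in participants}
    rho_v = config.latent_visit_corr
    scale = np.sqrt(1 - rho_v**2)

    factor_rows = np.empty((len(metadata), 2))
    for i, (_, row) in enumerate(metadata.iterrows()):
        wobble = chol @ rng.standard_normal(2)
        factor_rows[i] = rho_v * base[row["participant"]] + scale * wobble
    factors = pd.DataFrame(factor_rows, index=metadata.index, columns=["ED", "SE"])

    resp_scale = np.sqrt(config.base_loading**2 + 1.0)
    values = np.empty((len(metadata), n_items), dtype=int)
    noise = rng.standard_normal((len(metadata), n_items))
    for i, (_, row) in enumerate(metadata.iterrows()):
        lam_c, nu_c = lam[row["site"]]
        for j, item in enumerate(ITEMS[:n_items]):
            eta = factor_rows[i, 0 if config.item_factor_map[item] == "ED" else 1]
            ystar = (lam_c[j] * eta + nu_c[j] + noise[i, j]) / resp_scale
            values[i, j] = int(np.searchsorted(LIKERT_THRESHOLDS, ystar))
    likert = pd.DataFrame(values, index=metadata.index, columns=ITEMS[:n_items])
    likert.insert(0, "cohort", metadata["site"].values)
    return likert, factors


def _build_taxonomy(config: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    """ASV identifiers with genus/species-bearing rank strings.

    Named look-alike taxa anchor the planted effects; remaining ASVs are
    spread over synthetic genera (several genera hold multiple ASVs so
    genus aggregation is exercised).
    """
    special = [
        ("B_uniformis_like", "Bacteroidetes", "Bacteroidaceae", "Bacteroides", "uniformis_like"),
        ("T_mayombei_like", "Firmicutes", "Peptostreptococcaceae", "Terrisporobacter", "mayombei_like"),
        ("P_timonensis_like", "Bacteroidetes", "Prevotellaceae", "Prevotella", "timonensis_like"),
        ("A_muciniphila_like", "Verrucomicrobia", "Akkermansiaceae", "Akkermansia", "muciniphila_like"),
    ]
    phyla = ["Firmicutes", "Bacteroidetes", "Actinobacteria", "Proteobacteria"]
    rows = []
    for asv_id, phy, fam, gen, sp in special:
        rows.append(
            dict(asv=asv_id, phylum=phy, family=fam, genus=gen, species=sp,
                 taxonomy=f"p__{phy};f__{fam};g__{gen};s__{sp}")
        )
    n_rest = config.n_asv - len(special)
    genus_of_asv = rng.integers(0, config.n_genera, size=n_rest)
    for k in range(n_rest):
        g = genus_of_asv[k]
        phy = phyla[g % len(phyla)]
        fam = f"Family{g // 2:02d}"
        gen = f"Genus{g:03d}"
        # a handful of unassigned-genus ASVs to exercise family pooling
        if k % 29 == 7:
            gen = ""
        rows.append(
            dict(asv=f"ASV{k + 1:04d}", phylum=phy, family=fam, genus=gen,
                 species=f"sp{k + 1:04d}",
                 taxonomy=f"p__{phy};f__{fam};g__{gen};s__sp{k + 1:04d}")
        )
    tax = pd.DataFrame(rows).set_index("asv")
    return tax


def generate_asv_table(
    config: StudyConfig,
    metadata: pd.DataFrame,
    factors: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Zero-inflated compositional counts with planted taxon-trait effects.

    Log-normal basis abundances carry genus-level covariance (ASVs in one
    genus share a genus factor) and a participant random intercept (ICC
    ``abundance_icc``) linking the T2/T3 pair. Planted effects shift a
    taxon's log-abundance linearly in the standardized target factor
    score. Counts are multinomial at a per-sample depth, then thinned by
    depth-dependent dropout p0 = logistic(a - b*log(depth)).
    """
    tax = _build_taxonomy(config, rng)
    asv_ids = list(tax.index)
    for taxon, target, _, _ in config.planted_effects:
        if taxon not in tax.index:
            raise ValueError(f"planted taxon {taxon!r} not in taxonomy")
        if target not in ("ED", "SE") and target not in CYTOKINES:
            raise ValueError(f"planted target {target!r} unknown")

    n_samples, n_asv = len(metadata), config.n_asv
    genus_codes = pd.factorize(tax["genus"].where(tax["genus"] != "", tax["family"]))[0]
    n_gen = genus_codes.max() + 1

    mu = rng.normal(0.0, 1.5, size=n_asv)
    participants = list(metadata["participant"].unique())
    b_pg = {p: rng.standard_normal(n_gen) for p in participants}

    icc = config.abundance_icc
    w_part, w_visit = np.sqrt(icc), np.sqrt(1 - icc)

    zstd = (factors - factors.mean()) / factors.std(ddof=0)

    counts = np.zeros((n_samples, n_asv), dtype=int)
    depths = rng.integers(config.depth_range[0], config.depth_range[1] + 1, size=n_samples)
    for i, (sample, row) in enumerate(metadata.iterrows()):
        v_sg = rng.standard_normal(n_gen)
        genus_eff = w_part * b_pg[row["participant"]] + w_visit * v_sg
        logab = mu + genus_eff[genus_codes] + 0.5 * rng.standard_normal(n_asv)
        for taxon, target, sign, mag in config.planted_effects:
            j = asv_ids.index(taxon)
            if target in ("ED", "SE"):
                logab[j] += sign * mag * zstd.loc[sample, target]
        p = np.exp(logab - logab.max())
        p /= p.sum()
        c = rng.multinomial(depths[i], p)
        p0 = 1.0 / (1.0 + np.exp(-(config.dropout_a - config.dropout_b * np.log(depths[i]))))
        c[rng.random(n_asv) < p0] = 0
        counts[i] = c

    table = pd.DataFrame(counts, index=metadata.index, columns=asv_ids)
    return table, tax


def generate_cytokines(
    config: StudyConfig,
    metadata: pd.DataFrame,
    factors: pd.DataFrame,
    asv_counts: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Log-normal 21-analyte panel for the T2 visit of every participant.

    A common immune factor loads positively on all analytes except the
    CXCL11-like one (negative loading), reproducing a single analyte
    anti-correlated with the rest. BMI enters as a linear confounder on
    the log scale; listed couplings tie an analyte to a planted taxon's
    standardized log relative abundance.
    """
    t2 = metadata[metadata["trimester"] == "T2"]
    n = len(t2)
    loadings = np.full(len(CYTOKINES), config.cytokine_loading)
    loadings[CYTOKINES.index("CXCL11")] = config.cxcl11_loading
    mu = rng.normal(3.0, 1.0, size=len(CYTOKINES))

    rel = asv_counts.loc[t2.index].div(asv_counts.loc[t2.index].sum(axis=1), axis=0)
    f_common = rng.standard_normal(n)
    eps = rng.standard_normal((n, len(CYTOKINES)))

    logc = mu + np.outer(f_common, loadings) + 0.35 * eps
    logc += config.cytokine_bmi_beta * (t2["bmi"].values - 30.0)[:, None]
    for analyte, taxon, coef in config.cytokine_coupling:
        if taxon in rel.columns:
            x = np.log(rel[taxon] + rel[rel > 0].min().min() / 2)
            xz = (x - x.mean()) / max(x.std(ddof=0), 1e-12)
            logc[:, CYTOKINES.index(analyte)] += coef * xz.values

    panel = pd.DataFrame(np.exp(logc), index=t2.index, columns=CYTOKINES)
    return panel


def simulate_study(config: StudyConfig | None = None, seed: int | None = None) -> SyntheticStudy:
    """Generate a complete synthetic study; deterministic under (config, seed)."""
    config = config or StudyConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    metadata = generate_covariates(config, rng)
    likert, factors = generate_latent_and_likert(config, metadata, rng)
    asv_counts, taxonomy = generate_asv_table(config, metadata, factors, rng)
    cytokines = generate_cytokines(config, metadata, factors, asv_counts, rng)
    lam = _loading_matrices(config)
    truth = {
        "config": {
            k: (sorted(v) if isinstance(v, frozenset) else v)
            for k, v in asdict(config).items()
            if k != "item_factor_map"
        },
        "item_factor_map": dict(config.item_factor_map),
        "loadings_urban": lam["urban"][0].tolist(),
        "loadings_suburban": lam["suburban"][0].tolist(),
        "intercepts_urban": lam["urban"][1].tolist(),
        "intercepts_suburban": lam["suburban"][1].tolist(),
    }
    return SyntheticStudy(metadata, likert, factors, asv_counts, taxonomy, cytokines, truth)


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write all study tables as TSV plus a JSON truth file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.metadata.to_csv(outdir / "metadata.tsv", sep="\t")
    study.likert.to_csv(outdir / "likert.tsv", sep="\t")
    study.factors.to_csv(outdir / "factors_true.tsv", sep="\t")
    study.asv_counts.to_csv(outdir / "asv_counts.tsv", sep="\t")
    study.taxonomy.to_csv(outdir / "taxonomy.tsv", sep="\t")
    study.cytokines.to_csv(outdir / "cytokines.tsv", sep="\t")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(study.truth, fh, indent=1, default=str)
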