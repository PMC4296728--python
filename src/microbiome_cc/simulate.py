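"""Dirichlet-multinomial case-control community simulator.

Each sample's composition is drawn from a Dirichlet prior and sequenced to a
fixed read depth by a multinomial draw, giving compositional, overdispersed
count tables with the structure of rarefied 16S data.  Case samples use
concentrations multiplied by ``effect_size`` on a randomly chosen set of
affected taxa, so the group shift survives compositional renormalisation
coherently.  Metadata mirrors the covariate battery of an American-Gut-style
questionnaire (age, sex, race, BMI, region, diet, alcohol, smoking,
antibiotic recency, gluten/lactose/asthma flags) and the case label depends
on age through a logistic model so that age acts as a confounder.

``effect_size = 1`` is the exact null: case and control compositions are
exchangeable, which downstream calibration tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .table import Lineage, TaxonTable

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate_dataset", "simulate_tree"]

_PHYLA = [
    ("Firmicutes", 0.45),
    ("Bacteroidetes", 0.30),
    ("Proteobacteria", 0.12),
    ("Actinobacteria", 0.08),
    ("Verrucomicrobia", 0.03),
    ("Fusobacteria", 0.02),
]

# Table-1-style categorical vocabularies with realistic frequencies
_RACE = (
    ["Caucasian", "African American", "Hispanic", "Asian or Pacific Islander", "Other"],
    [0.927, 0.010, 0.015, 0.033, 0.015],
)
_REGION = (
    ["California", "Other western US", "Midwestern US", "Northeastern US",
     "Southern US", "Canada", "Europe", "Australia"],
    [0.198, 0.215, 0.158, 0.188, 0.202, 0.021, 0.011, 0.007],
)
_DIET = (
    ["Omnivore", "No red meat", "Vegan", "Vegetarian", "Pescetarian"],
    [0.796, 0.062, 0.028, 0.042, 0.072],
)
_ALCOHOL = (
    ["Never", "Rarely", "Occasionally", "Regularly", "Daily"],
    [0.213, 0.245, 0.206, 0.197, 0.139],
)
_SMOKING = (["Never", "Rarely", "More than rarely"], [0.959, 0.024, 0.017])
_ANTIBIOTIC = (
    ["None in past year", "2-6 months", "7-12 months"],
    [0.763, 0.108, 0.129],
)
_WEIGHT = (["Remained stable", "Decreased > 10 lb", "Increased > 10 lb"], [0.848, 0.101, 0.051])


@dataclass
class SimulationConfig:
    """Parameters of the case-control community simulator.

    ``base_concentration`` may be a scalar (symmetric Dirichlet), a vector of
    per-taxon concentrations, or None for a seeded lognormal concentration
    profile (sigma = 1, total concentration 50) — strongly uneven, as real
    gut compositions are.
    """

    n_cases: int = 50
    n_controls: int = 50
    n_taxa: int = 100
    depth: int = 10_000
    effect_taxa_fraction: float = 0.1
    effect_size: float = 1.0
    base_concentration: float | np.ndarray | None = None
    age_effect: float = -0.04  # log-odds of case status per year of age
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_cases + self.n_controls < 4:
            raise ValueError("need at least 4 samples in total")
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if not 0 <= self.effect_taxa_fraction <= 1:
            raise ValueError("effect_taxa_fraction must lie in [0, 1]")
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1 (fold change on concentrations)")
        if self.base_concentration is not None:
            conc = np.atleast_1d(np.asarray(self.base_concentration, dtype=float))
            if (conc <= 0).any():
                raise ValueError("base_concentration must be positive")
            if conc.size not in (1, self.n_taxa):
                raise ValueError("base_concentration must be scalar or length n_taxa")

    def concentrations(self) -> np.ndarray:
        """The per-taxon Dirichlet concentration vector this config implies."""
        if self.base_concentration is None:
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, 7]))
            w = rng.lognormal(mean=0.0, sigma=1.0, size=self.n_taxa)
            return 50.0 * w / w.sum()
        conc = np.atleast_1d(np.asarray(self.base_concentration, dtype=float))
        if conc.size == 1:
            conc = np.full(self.n_taxa, float(conc[0]))
        return conc.copy()


@dataclass
class SimulatedDataset:
    """A simulated study: counts table, metadata, lineages, and ground truth."""

    table: TaxonTable
    metadata: pd.DataFrame
    lineages: dict[str, Lineage]
    affected_taxa: list[str]
    concentrations: np.ndarray
    config: SimulationConfig


def _make_lineages(n_taxa: int, rng: np.random.Generator) -> tuple[list[str], dict[str, Lineage]]:
    """Random but nested 7-rank greengenes-style paths, ~10% unnamed at
    genus/species (the ``g__;s__`` pattern seen in real tables)."""
    phyla, weights = zip(*_PHYLA)
    ids, lineages = [], {}
    for i in range(n_taxa):
        p = rng.choice(len(phyla), p=np.array(weights))
        pname = phyla[p]
        c = rng.integers(1, 3)
        o = rng.integers(1, 3)
        f = rng.integers(1, 4)
        g = rng.integers(1, 5)
        gname = "" if rng.random() < 0.1 else f"{pname[:4]}g{c}{o}{f}{g}"
        sname = "" if (not gname or rng.random() < 0.1) else f"sp{i:04d}"
        s = (
            f"k__Bacteria;p__{pname};c__{pname[:4]}c{c};o__{pname[:4]}o{c}{o};"
            f"f__{pname[:4]}f{c}{o}{f};g__{gname};s__{sname}"
        )
        otu = f"OTU{i:05d}"
        ids.append(otu)
        lineages[otu] = Lineage.parse(s)
    return ids, lineages


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw a full case-control dataset under ``config``.

    Counts are multinomial at exactly ``config.depth`` reads per sample from
    Dirichlet compositions; cases multiply the concentrations of the affected
    taxa by ``effect_size``.  Case status is assigned to exactly ``n_cases``
    samples, sampled without replacement with weights proportional to
    exp(age_effect * age), so prevalence falls (or rises) with age.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    taxon_ids, lineages = _make_lineages(config.n_taxa, rng)
    alpha = config.concentrations()

    n_affected = int(round(config.effect_taxa_fraction * config.n_taxa))
    affected_idx = np.sort(rng.choice(config.n_taxa, size=n_affected, replace=False))
    affected = [taxon_ids[i] for i in affected_idx]

    sample_ids = [f"S{i:05d}" for i in range(n)]
    age = np.clip(rng.normal(46, 16, size=n), 4, 99).round(1)

    # exactly n_cases cases, age-weighted (conditional logistic link)
    logits = config.age_effect * age
    w = np.exp(logits - logits.max())
    case_pos = rng.choice(n, size=config.n_cases, replace=False, p=w / w.sum())
    is_case = np.zeros(n, dtype=bool)
    is_case[case_pos] = True

    alpha_case = alpha.copy()
    alpha_case[affected_idx] *= config.effect_size

    counts = np.empty((n, config.n_taxa), dtype=np.int64)
    for i in range(n):
        comp = rng.dirichlet(alpha_case if is_case[i] else alpha)
        counts[i] = rng.multinomial(config.depth, comp)

    data = pd.DataFrame(counts, index=sample_ids, columns=taxon_ids)
    table = TaxonTable(data, lineages, mode="counts")

    def cat(vocab):
        values, probs = vocab
        return rng.choice(values, size=n, p=np.array(probs) / np.sum(probs))

    metadata = pd.DataFrame(
        {
            "AGE": age,
            "SEX": rng.choice(["male", "female"], size=n, p=[0.443, 0.557]),
            "RACE": cat(_RACE),
            "BMI": np.clip(rng.normal(24, 5, size=n), 15, 60).round(1),
            "BODY_SITE": "UBERON:feces",
            "ANTIBIOTIC_SELECT": cat(_ANTIBIOTIC),
            "DIABETES": "no",
            "IBD": "no",
            "CSECTION": np.where(is_case, "yes", "no"),
            "APPENDIX_REMOVED": rng.choice(["yes", "no"], size=n, p=[0.14, 0.86]),
            "HOST_SUBJECT_ID": [f"P{i:05d}" for i in range(n)],
            "REGION": cat(_REGION),
            "DIET_TYPE": cat(_DIET),
            "ALCOHOL_FREQUENCY": cat(_ALCOHOL),
            "SMOKING_FREQUENCY": cat(_SMOKING),
            "WEIGHT_CHANGE": cat(_WEIGHT),
            "GLUTEN": rng.choice(["yes", "no"], size=n, p=[0.192, 0.808]),
            "LACTOSE": rng.choice(["yes", "no"], size=n, p=[0.176, 0.824]),
            "ASTHMA": rng.choice(["yes", "no"], size=n, p=[0.083, 0.917]),
        },
        index=pd.Index(sample_ids, name="#SampleID"),
    )
    return SimulatedDataset(table, metadata, lineages, affected, alpha, config)


def simulate_tree(taxa, seed: int = 0) -> str:
    """Random rooted binary tree over ``taxa`` as a newick string.

    Topology by uniform random joins, branch lengths iid Exponential(1);
    deterministic given the seed.
    """
    taxa = list(taxa)
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    if len(set(taxa)) != len(taxa):
        dup = sorted({t for t in taxa if taxa.count(t) > 1})
        raise ValueError(f"duplicate taxon names: {dup}")
    rng = np.random.default_rng(seed)
    nodes = [f"{t}:{rng.exponential(1.0):.6f}" for t in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        if len(nodes) == 0:
            nodes.append(f"({left},{right}):0.0")
        else:
            nodes.append(f"({left},{right}):{rng.exponential(1.0):.6f}")
    newick = nodes[0].rsplit(":", 1)[0] + ";"
    return newick
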