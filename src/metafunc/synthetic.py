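"""Compositional simulator for functional-abundance cohorts.

Generates sample x function count matrices shaped like a shotgun-metagenome
functional (COG) profile of a four-group clinical cohort, together with a
category map and a clinical-index table, with planted structure so every
downstream stage (differential abundance, co-occurrence networks, biomarker
selection) can be tested against known truth:

* per-sample latent log-abundances are Gaussian with block-structured
  correlation (a shared factor per block), giving log-normal abundances;
* planted enrichments multiply a function's abundance by a fold factor in
  one group;
* latent abundances are closed to proportions and counts drawn multinomially
  at a fixed sequencing depth — abundance data are compositional;
* clinical indices are linear in the rank-transform of a linked function's
  relative abundance plus Gaussian noise, so the planted Spearman link
  strength is controlled directly.

Default cohort layout is 15/22/15/13 samples for groups HC / IBS-D / DEP /
COMO, matching the study design this pipeline targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_core import (
    CLASS_OF_CATEGORY,
    CategoryMap,
    ClinicalTable,
    FunctionalProfile,
    write_abundance_table,
    write_category_map,
    write_clinical_table,
)

DEFAULT_GROUP_SIZES = (15, 22, 15, 13)
DEFAULT_GROUP_LABELS = ("HC", "IBS-D", "DEP", "COMO")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    ``enrichments`` are ``(function_id, group_label, fold)`` with fold > 0;
    ``blocks`` are ``(member_function_ids, rho)`` with within-block latent
    correlation rho in (0,1); ``clinical_links`` are
    ``(index_name, function_id, sign, strength)`` with sign +1/-1 and
    strength in (0,1) — the target Spearman correlation magnitude.
    """

    group_sizes: tuple[int, ...] = DEFAULT_GROUP_SIZES
    group_labels: tuple[str, ...] = DEFAULT_GROUP_LABELS
    n_functions: int = 200
    depth: int = 100_000
    mu_sigma: float = 1.0  # spread of base log-abundance across functions
    sample_sigma: float = 0.7  # per-sample biological log-scale noise
    enrichments: list = field(default_factory=list)
    blocks: list = field(default_factory=list)
    clinical_links: list = field(default_factory=list)
    noise_indices: int = 0  # extra clinical columns of pure noise
    seed: int = 0

    def __post_init__(self) -> None:
        self.group_sizes = tuple(int(n) for n in self.group_sizes)
        self.group_labels = tuple(self.group_labels)
        if len(self.group_sizes) != len(self.group_labels):
            raise ValueError("group_sizes and group_labels differ in length")
        if any(n < 2 for n in self.group_sizes):
            raise ValueError("every group needs at least 2 samples")
        if self.n_functions < 2:
            raise ValueError("need at least 2 functions")
        for fid, grp, fold in self.enrichments:
            if fold <= 0:
                raise ValueError(f"fold factor must be > 0 for {fid!r}")
            if grp not in self.group_labels:
                raise ValueError(f"enrichment references unknown group {grp!r}")
        for members, rho in self.blocks:
            if not 0 < rho < 1:
                raise ValueError("block correlation strength must lie in (0,1)")
        for name, fid, sign, strength in self.clinical_links:
            if sign not in (1, -1):
                raise ValueError(f"link sign must be +1 or -1 for {name!r}")
            if not 0 < strength < 1:
                raise ValueError(f"link strength must lie in (0,1) for {name!r}")

    @property
    def function_ids(self) -> list[str]:
        return [f"COG{i + 1:04d}" for i in range(self.n_functions)]

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["group_sizes"] = list(self.group_sizes)
        doc["group_labels"] = list(self.group_labels)
        doc["enrichments"] = [list(e) for e in self.enrichments]
        doc["blocks"] = [[list(m), float(r)] for m, r in self.blocks]
        doc["clinical_links"] = [list(l) for l in self.clinical_links]
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["enrichments"] = [tuple(e) for e in doc.get("enrichments", [])]
        doc["blocks"] = [(list(m), float(r)) for m, r in doc.get("blocks", [])]
        doc["clinical_links"] = [tuple(l) for l in doc.get("clinical_links", [])]
        return cls(**doc)


@dataclass
class SyntheticDataset:
    """A generated cohort plus the truth needed to verify recovery."""

    profile: FunctionalProfile
    clinical: ClinicalTable
    category_map: CategoryMap
    config: SimulationConfig
    #: group x function expected relative abundances under the generating model
    expected_proportions: pd.DataFrame

    def expected_group_ratio(self, function_id: str, group_a: str, group_b: str) -> float:
        """Expected relative-abundance ratio between two groups for a function."""
        pa = self.expected_proportions.at[group_a, function_id]
        pb = self.expected_proportions.at[group_b, function_id]
        return float(pa / pb)


def default_category_map(function_ids) -> CategoryMap:
    """Round-robin assignment of functions to the 26 COG categories."""
    cats = sorted(CLASS_OF_CATEGORY)
    rows = []
    for i, fid in enumerate(function_ids):
        cat = cats[i % len(cats)]
        rows.append((fid, cat, CLASS_OF_CATEGORY[cat]))
    frame = pd.DataFrame(rows, columns=["function", "category", "class"])
    return CategoryMap(frame.set_index("function"))


def generate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Draw one cohort from the generative model; reproducible from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    fids = cfg.function_ids
    fid_index = {f: j for j, f in enumerate(fids)}
    for fid, grp, fold in cfg.enrichments:
        if fid not in fid_index:
            raise ValueError(f"enrichment references unknown function {fid!r}")
    for members, rho in cfg.blocks:
        for fid in members:
            if fid not in fid_index:
                raise ValueError(f"block references unknown function {fid!r}")
    for name, fid, sign, strength in cfg.clinical_links:
        if fid not in fid_index:
            raise ValueError(f"clinical link references unknown function {fid!r}")

    n_samples = sum(cfg.group_sizes)
    group = np.repeat(cfg.group_labels, cfg.group_sizes)
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]

    # base log-abundance per function (spread across functions)
    mu = rng.normal(0.0, cfg.mu_sigma, size=cfg.n_functions)

    # latent per-sample Gaussian noise with shared block factors:
    # z_j = sqrt(rho) * u_block + sqrt(1-rho) * e_j  within a block
    z = rng.standard_normal((n_samples, cfg.n_functions))
    for members, rho in cfg.blocks:
        cols = [fid_index[f] for f in members]
        shared = rng.standard_normal(n_samples)
        z[:, cols] = np.sqrt(rho) * shared[:, None] + np.sqrt(1 - rho) * z[:, cols]

    log_fold = np.zeros((len(cfg.group_labels), cfg.n_functions))
    for fid, grp, fold in cfg.enrichments:
        log_fold[cfg.group_labels.index(grp), fid_index[fid]] += np.log(fold)

    group_idx = np.repeat(np.arange(len(cfg.group_labels)), cfg.group_sizes)
    log_abund = mu[None, :] + cfg.sample_sigma * z + log_fold[group_idx]
    abund = np.exp(log_abund)
    props = abund / abund.sum(axis=1, keepdims=True)

    counts = np.vstack([rng.multinomial(cfg.depth, p) for p in props])
    profile = FunctionalProfile(
        pd.DataFrame(counts, index=sample_ids, columns=fids),
        pd.Series(group, index=sample_ids, name="group"),
        "counts",
    )

    # truth: expected relative abundance per group, from log-normal means
    exp_abund = np.exp(mu[None, :] + log_fold + cfg.sample_sigma**2 / 2)
    exp_props = exp_abund / exp_abund.sum(axis=1, keepdims=True)
    expected = pd.DataFrame(exp_props, index=list(cfg.group_labels), columns=fids)

    # clinical indices: rank-linear in the linked function's relative
    # abundance. Ranks are taken and standardized within each study group so
    # the planted strength is the within-group Spearman correlation — the
    # scale on which biomarker selection screens clinical links. (Cohort
    # ranks would be compressed within an enriched group, attenuating the
    # planted link exactly where it is measured.)
    rel = counts / counts.sum(axis=1, keepdims=True)
    clinical_cols = {}
    for name, fid, sign, strength in cfg.clinical_links:
        x = rel[:, fid_index[fid]]
        zr = np.empty(n_samples)
        for gi in range(len(cfg.group_labels)):
            sel = group_idx == gi
            ranks = pd.Series(x[sel]).rank().to_numpy()
            zr[sel] = (ranks - ranks.mean()) / ranks.std()
        noise = rng.standard_normal(n_samples)
        clinical_cols[name] = sign * strength * zr + np.sqrt(1 - strength**2) * noise
    for k in range(cfg.noise_indices):
        clinical_cols[f"noise_{k + 1}"] = rng.standard_normal(n_samples)
    clinical = ClinicalTable(
        pd.DataFrame(clinical_cols, index=sample_ids, dtype=float),
        profile.group.copy(),
    )

    return SyntheticDataset(
        profile=profile,
        clinical=clinical,
        category_map=default_category_map(fids),
        config=cfg,
        expected_proportions=expected,
    )


def write_fixture(dataset: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Persist the three TSVs plus a YAML truth file; paths keyed by role."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": out / "abundance.tsv",
        "clinical": out / "clinical.tsv",
        "category_map": out / "category_map.tsv",
        "truth": out / "truth.yaml",
    }
    write_abundance_table(dataset.profile, paths["abundance"])
    write_clinical_table(dataset.clinical, paths["clinical"])
    write_category_map(dataset.category_map, paths["category_map"])
    cfg = dataset.config
    truth = {
        "config": {
            "group_sizes": list(cfg.group_sizes),
            "group_labels": list(cfg.group_labels),
            "n_functions": cfg.n_functions,
            "depth": cfg.depth,
            "mu_sigma": cfg.mu_sigma,
            "sample_sigma": cfg.sample_sigma,
            "enrichments": [list(e) for e in cfg.enrichments],
            "blocks": [[list(m), float(r)] for m, r in cfg.blocks],
            "clinical_links": [list(l) for l in cfg.clinical_links],
            "noise_indices": cfg.noise_indices,
            "seed": cfg.seed,
        },
        "expected_proportions": {
            g: {f: float(v) for f, v in row.items()}
            for g, row in dataset.expected_proportions.iterrows()
        },
    }
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=False)
    return paths


def example_config(seed: int = 0, n_functions: int = 200) -> SimulationConfig:
    """A cohort emulating the target study's structure.

    Two functions enriched in IBS-D and one in DEP (fold 3), a correlated
    block of ten functions, and clinical indices linked to the enriched
    functions (severity scores positively, fecal SCFAs negatively for the
    DEP-enriched function).
    """
    fids = [f"COG{i + 1:04d}" for i in range(n_functions)]
    block = fids[20:30]
    return SimulationConfig(
        n_functions=n_functions,
        enrichments=[
            (fids[0], "IBS-D", 3.0),
            (fids[1], "IBS-D", 3.0),
            (fids[2], "DEP", 3.0),
        ],
        blocks=[(block, 0.9)],
        clinical_links=[
            ("IBS-SSS", fids[0], 1, 0.8),
            ("bloating", fids[1], 1, 0.7),
            ("SDS", fids[2], 1, 0.8),
            ("propionate", fids[2], -1, 0.6),
        ],
        noise_indices=3,
        seed=seed,
    )
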