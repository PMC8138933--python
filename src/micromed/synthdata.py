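"""Seeded synthetic generator for a 2-community x 4-diet gnotobiotic design.

The generator emulates the statistical structure the downstream analyses
assume: a rooted multi-rank taxonomy (phylum -> genus) with branch lengths; a
samples x genera count table drawn from a logistic-normal composition (shared
baseline + community-specific structural zeros + diet-responsive log-fold
effects + correlated sample noise) multinomially sampled at a varying
sequencing depth; phenotypes driven by direct community/diet/batch effects plus
an optional taxa-mediated log-contrast path; and continuous omics matrices with
planted latent-factor blocks for module-detection recovery.  Every function is
a pure function of its arguments including the seed, and a GroundTruth record
is produced for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .preprocess import zero_replace

__all__ = [
    "StudyDesign",
    "GroundTruth",
    "make_taxonomy",
    "lineages_from_tree",
    "design_metadata",
    "sample_counts",
    "make_phenotypes",
    "make_omics",
    "write_dataset",
]

RANKS = ("phylum", "class", "order", "family", "genus")
RANK_CODES = ("p", "c", "o", "f", "g")


@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout: 2 communities x 4 diets, n_per_cell mice each."""

    n_per_cell: int = 8
    communities: tuple = ("SubA", "SubB")
    diets: tuple = ("C", "I", "P", "Af")
    n_batches: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_per_cell < 3:
            raise ValueError("n_per_cell must be >= 3")
        if len(self.communities) != 2 or len(self.diets) < 2:
            raise ValueError("design needs 2 communities and >= 2 diets")

    @property
    def n_samples(self) -> int:
        return self.n_per_cell * len(self.communities) * len(self.diets)


@dataclass
class GroundTruth:
    """Record of planted structure, serialized alongside generated data."""

    community_core_taxa: dict = field(default_factory=dict)
    diet_responders: dict = field(default_factory=dict)
    beta_true: dict = field(default_factory=dict)
    phenotype_effects: dict = field(default_factory=dict)
    mediating_node: str | None = None
    module_labels_true: dict = field(default_factory=dict)
    latent_factors: dict = field(default_factory=dict)

    def validate(self):
        for name, beta in self.beta_true.items():
            if abs(sum(beta.values())) > 1e-12:
                raise ValueError(f"beta_true[{name}] does not sum to zero")

    def to_json(self, path):
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path):
        return cls(**json.loads(Path(path).read_text()))


def _partition(n_children: int, n_parents: int, rng) -> np.ndarray:
    """Random surjection child -> parent (every parent gets >= 1 child)."""
    assign = np.concatenate([
        np.arange(n_parents),
        rng.integers(0, n_parents, size=n_children - n_parents),
    ])
    rng.shuffle(assign)
    return assign


def make_taxonomy(n_genera: int, n_families: int, seed: int) -> TreeNode:
    """Random rooted taxonomy with ranks phylum/class/order/family/genus.

    Intermediate rank sizes are chosen so that a 45-genus / 25-family call
    produces a tree shaped like a realistic genus-level 16S survey (around
    5 phyla and 11 classes/orders).  Genera are leaves; internal nodes carry
    rank-prefixed names (``p__P1`` ... ``f__F1``); branch lengths are positive.
    """
    if not (n_genera >= n_families >= 2):
        raise ValueError("need n_genera >= n_families >= 2")
    rng = np.random.default_rng(seed)
    n_phyla = int(min(n_families, max(2, round(n_families / 5))))
    n_mid = int(min(n_families, max(n_phyla, round(np.sqrt(n_phyla * n_families)))))
    sizes = {"phylum": n_phyla, "class": n_mid, "order": n_mid,
             "family": n_families, "genus": n_genera}

    parents = {}
    rank_list = list(RANKS)
    for upper, lower in zip(rank_list[:-1], rank_list[1:]):
        parents[lower] = _partition(sizes[lower], sizes[upper], rng)

    def name(rank_idx, i):
        return f"{RANK_CODES[rank_idx]}__{RANKS[rank_idx][0].upper()}{i + 1}"

    nodes = {}
    root = TreeNode(name="root")
    for ri, rank in enumerate(RANKS):
        for i in range(sizes[rank]):
            node = TreeNode(name=name(ri, i), length=float(rng.uniform(0.2, 1.0)))
            nodes[(rank, i)] = node
            if ri == 0:
                root.append(node)
            else:
                nodes[(RANKS[ri - 1], int(parents[rank][i]))].append(node)
    return root


def read_taxonomy(source) -> TreeNode:
    """Read a Newick taxonomy preserving rank-prefixed names (``f__F1`` etc.).

    Plain ``TreeNode.read`` converts unquoted underscores to spaces per the
    Newick standard, which would mangle QIIME-style labels.
    """
    return TreeNode.read(source, convert_underscores=False)


def lineages_from_tree(tree: TreeNode) -> pd.Series:
    """QIIME-style 5-rank lineage string for every genus leaf."""
    out = {}
    for leaf in tree.tips():
        path = [a.name for a in leaf.ancestors() if a.name != "root"][::-1]
        out[leaf.name] = ";".join(path + [leaf.name])
    return pd.Series(out, name="lineage")


def design_metadata(design: StudyDesign) -> pd.DataFrame:
    """Deterministic sample sheet: one row per mouse with community/diet/batch."""
    rows = []
    i = 0
    for comm in design.communities:
        for diet in design.diets:
            for k in range(design.n_per_cell):
                rows.append({
                    "sample": f"{comm}_{diet}_{k + 1:02d}",
                    "community": comm,
                    "diet": diet,
                    "batch": f"B{(i % design.n_batches) + 1}",
                })
                i += 1
    return pd.DataFrame(rows).set_index("sample")


def sample_counts(design: StudyDesign, tree: TreeNode,
                  depth_range=(5_000, 40_000), seed: int = 0, *,
                  diet_effect: float = 1.0, exclusive_frac: float = 0.3,
                  responder_frac: float = 0.25, noise_sd: float = 0.6,
                  n_latent: int = 3, community_shift_sd: float = 0.5,
                  mediating_family: str | None = None,
                  family_shift: float = 1.5):
    """Draw a samples x genera count table from the logistic-normal model.

    Per sample ``s`` in community ``c`` on diet ``d``::

        logit_j = base_j + shift_{c,j} + effect_{d,j} + (Lambda f_s + e_s)_j

    with ``effect`` nonzero only for designated responder taxa and
    ``shift = -inf`` (structural zero) for taxa exclusive to the other
    community.  Counts are multinomial draws of the softmax composition at a
    uniform-random depth in ``depth_range``.  Latent factors ``f_s`` induce
    taxa covariance.

    ``mediating_family`` plants an exposure -> clade path for mediation
    recovery: in the second community the first genus of that family gains
    ``+family_shift`` log units and the second loses the same amount, so the
    family's internal log-ratio carries the community signal.  The node is
    recorded as ``GroundTruth.mediating_node``.

    Returns ``(counts, metadata, GroundTruth)``.
    """
    lo, hi = int(depth_range[0]), int(depth_range[1])
    if lo <= 0 or hi < lo:
        raise ValueError("depth_range must be positive and ordered")
    rng = np.random.default_rng(seed)
    taxa = [leaf.name for leaf in tree.tips()]
    p = len(taxa)
    meta = design_metadata(design)

    base = rng.normal(0.0, 1.5, size=p)
    shift = {c: rng.normal(0.0, community_shift_sd, size=p)
             for c in design.communities}

    n_excl = int(np.floor(exclusive_frac * p))
    excl_idx = rng.choice(p, size=n_excl, replace=False)
    half = n_excl // 2
    cores = {design.communities[0]: sorted(taxa[j] for j in excl_idx[:half]),
             design.communities[1]: sorted(taxa[j] for j in excl_idx[half:])}
    mask = {c: np.zeros(p, bool) for c in design.communities}
    other = {design.communities[0]: design.communities[1],
             design.communities[1]: design.communities[0]}
    for c in design.communities:
        for t in cores[c]:
            mask[other[c]][taxa.index(t)] = True  # absent from the other community

    shared = np.setdiff1d(np.arange(p), excl_idx)
    n_resp = int(np.floor(responder_frac * p))
    resp_idx = rng.choice(shared, size=min(n_resp, shared.size), replace=False)
    effects = {d: np.zeros(p) for d in design.diets}
    responders = {}
    for j in resp_idx:
        per_diet = rng.normal(0.0, 1.0, size=len(design.diets))
        per_diet -= per_diet.mean()  # diet effects are contrasts around the base
        for d, e in zip(design.diets, per_diet):
            effects[d][j] = diet_effect * e
        responders[taxa[j]] = {d: float(diet_effect * e)
                               for d, e in zip(design.diets, per_diet)}

    mediating_node = None
    med_shift = np.zeros(p)
    if mediating_family is not None:
        fam = tree.find(mediating_family)
        fam_leaves = [t.name for t in fam.tips()]
        if len(fam_leaves) < 2:
            raise ValueError(f"{mediating_family} needs >= 2 genera to mediate")
        g_up, g_down = fam_leaves[0], fam_leaves[1]
        for g in (g_up, g_down):
            mask[design.communities[0]][taxa.index(g)] = False
            mask[design.communities[1]][taxa.index(g)] = False
        med_shift[taxa.index(g_up)] = family_shift
        med_shift[taxa.index(g_down)] = -family_shift
        mediating_node = mediating_family

    loading = rng.normal(0.0, 0.4, size=(p, n_latent))
    counts = np.zeros((design.n_samples, p), dtype=np.int64)
    for i, (sid, row) in enumerate(meta.iterrows()):
        eps = loading @ rng.normal(size=n_latent) + rng.normal(0.0, noise_sd, size=p)
        logit = base + shift[row.community] + effects[row.diet] + eps
        if row.community == design.communities[1]:
            logit = logit + med_shift
        logit = np.where(mask[row.community], -np.inf, logit)
        prob = np.exp(logit - np.max(logit[np.isfinite(logit)]))
        prob[~np.isfinite(prob)] = 0.0
        prob /= prob.sum()
        depth = int(rng.integers(lo, hi + 1))
        counts[i] = rng.multinomial(depth, prob)

    table = pd.DataFrame(counts, index=meta.index, columns=taxa)
    truth = GroundTruth(community_core_taxa=cores, diet_responders=responders,
                        mediating_node=mediating_node)
    return table, meta, truth


def make_phenotypes(taxa: pd.DataFrame, meta: pd.DataFrame, beta_true,
                    mediation_strength: float = 0.0, noise_sd: float = 1.0,
                    seed: int = 0, *, community_effect: float = 1.0,
                    diet_effects=None, batch_effect: float = 0.3,
                    name: str = "phenotype"):
    """Phenotype = community + diet + batch + mediated log-contrast + noise.

    ``beta_true`` (aligned with the taxa columns) must sum to zero so that the
    planted taxa path is a genuine log-contrast signal.  Returns
    ``(phenotype Series, effects dict)``; the dict is suitable for storing in
    GroundTruth.phenotype_effects / beta_true.
    """
    beta = np.asarray(beta_true, float)
    if beta.shape != (taxa.shape[1],):
        raise ValueError("beta_true must align with taxa columns")
    if abs(beta.sum()) > 1e-8:
        raise ValueError("beta_true must sum to zero")
    if noise_sd < 0 or mediation_strength < 0:
        raise ValueError("mediation_strength and noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    communities = sorted(meta["community"].unique())
    diets = sorted(meta["diet"].unique())
    if diet_effects is None:
        diet_effects = {d: 0.0 for d in diets}
    batches = sorted(meta["batch"].unique())
    batch_shift = {b: batch_effect * k for k, b in enumerate(batches)}

    z = np.log(np.asarray(zero_replace(taxa)))
    y = (community_effect * (meta["community"] == communities[-1]).to_numpy(float)
         + meta["diet"].map(diet_effects).to_numpy(float)
         + meta["batch"].map(batch_shift).to_numpy(float)
         + mediation_strength * (z @ beta)
         + rng.normal(0.0, noise_sd, size=len(meta)) * (noise_sd > 0))
    effects = {
        "community_effect": community_effect,
        "diet_effects": dict(diet_effects),
        "batch_shift": batch_shift,
        "mediation_strength": mediation_strength,
        "noise_sd": noise_sd,
        "beta_true": {t: float(b) for t, b in zip(taxa.columns, beta)},
    }
    return pd.Series(y, index=meta.index, name=name), effects


def make_omics(design: StudyDesign, n_features: int, n_blocks: int,
               within_block_corr: float = 0.7, taxa_driver: dict | None = None,
               seed: int = 0, *, taxa_logrel: pd.DataFrame | None = None,
               block_size: int | None = None, prefix: str = "feat"):
    """Latent-factor block omics matrix with pathway annotations.

    Each block ``b`` has a per-sample latent factor ``f_b`` (standard normal,
    or a taxa log-contrast when ``taxa_driver[b]`` supplies zero-sum weights
    and ``taxa_logrel`` the log relative abundances); block features are
    ``sqrt(rho) * f_b + sqrt(1 - rho) * noise`` so the within-block correlation
    is ``rho``.  Features outside blocks are independent noise.  Returns
    ``(matrix, annotation, GroundTruth)`` with true block labels (0 = noise)
    and the latent factors recorded.
    """
    if not 0 <= within_block_corr < 1 + 1e-12:
        raise ValueError("within_block_corr must lie in [0, 1)")
    if n_blocks < 0:
        raise ValueError("n_blocks must be nonnegative")
    if n_blocks and block_size is None:
        block_size = n_features // n_blocks
    if n_blocks and (block_size < 20 or n_blocks * block_size > n_features):
        raise ValueError("infeasible block sizes (min module size is 20)")
    rng = np.random.default_rng(seed)
    n = design.n_samples
    meta = design_metadata(design)

    rho = within_block_corr
    values = rng.normal(size=(n, n_features))
    labels = np.zeros(n_features, int)
    factors = {}
    for b in range(n_blocks):
        cols = slice(b * block_size, (b + 1) * block_size)
        labels[cols] = b + 1
        if taxa_driver is not None and b in taxa_driver:
            if taxa_logrel is None:
                raise ValueError("taxa_driver requires taxa_logrel")
            w = np.asarray(taxa_driver[b], float)
            if abs(w.sum()) > 1e-8:
                raise ValueError("taxa_driver weights must sum to zero")
            f = np.asarray(taxa_logrel) @ w
            f = (f - f.mean()) / f.std()
        else:
            f = rng.normal(size=n)
        factors[f"block_{b + 1}"] = [float(v) for v in f]
        values[:, cols] = np.sqrt(rho) * f[:, None] + np.sqrt(1 - rho) * values[:, cols]

    names = [f"{prefix}_{j + 1:04d}" for j in range(n_features)]
    matrix = pd.DataFrame(values, index=meta.index, columns=names)
    annotation = pd.DataFrame({
        "feature": names,
        "pathway": [f"pathway_{l}" if l else "unannotated" for l in labels],
    }).set_index("feature")
    truth = GroundTruth(
        module_labels_true={f: int(l) for f, l in zip(names, labels)},
        latent_factors=factors,
    )
    return matrix, annotation, truth


def write_dataset(out_dir, counts: pd.DataFrame, meta: pd.DataFrame,
                  tree: TreeNode, truth: GroundTruth,
                  omics: pd.DataFrame | None = None,
                  annotation: pd.DataFrame | None = None,
                  phenotypes: pd.DataFrame | None = None):
    """Serialize a generated dataset as plain-text TSV/Newick/JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts.to_csv(out / "counts.tsv", sep="\t")
    meta.to_csv(out / "metadata.tsv", sep="\t")
    lineages_from_tree(tree).to_csv(out / "lineages.tsv", sep="\t")
    tree.write(str(out / "taxonomy.nwk"))
    truth.to_json(out / "ground_truth.json")
    if omics is not None:
        omics.to_csv(out / "omics.tsv", sep="\t")
    if annotation is not None:
        annotation.to_csv(out / "annotations.tsv", sep="\t")
    if phenotypes is not None:
        phenotypes.to_csv(out / "phenotypes.tsv", sep="\t")
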