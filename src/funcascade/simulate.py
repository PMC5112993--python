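"""Synthetic benchmark datasets with guilt-by-association structure.

The generator emulates the statistical features the cascade exploits in a
real annotated proteome, without modelling any actual biology:

* a skewed multi-label category distribution (defaults follow the per-
  category protein counts of the mouse FunCat reference annotation, where
  two categories cover well over half the proteins and the mean protein
  carries about three labels);
* *label profiles* — functional modules that assign correlated label sets.
  Real annotations are strongly co-occurring (a ribosomal protein is
  simultaneously "protein synthesis" and "subcellular localization"), and
  interaction partners tend to share whole profiles, not single labels;
* homology clusters whose members share a profile and exchange similarity
  hits with scores that increase with label overlap;
* a weighted interaction network in which a tunable fraction
  ``gba_strength`` of edges joins label-sharing pairs.  Sharing partners are
  drawn uniformly among sharing pairs, so setting ``gba_strength`` equal to
  the label-sharing rate of random pairs reproduces a completely
  uninformative random network in distribution;
* a fraction of orphan proteins with neither hits nor edges, reachable only
  through the PseAAC branch; all sequences are drawn from label-dependent
  residue-usage tilts so the composition carries a weak function signal.

Everything is driven by one seed; two calls with equal configs produce
byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import FUNCAT_CATEGORIES, FunctionScheme
from .io import Dataset
from .pseaac import AMINO_ACIDS


def _default_weights() -> tuple[float, ...]:
    return tuple(float(count) for _, _, count in FUNCAT_CATEGORIES)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic dataset generator.

    ``category_weights`` must align with the scheme's categories; fractions
    are of ``n_proteins``; ``mean_labels`` is the expected label-set size
    (1 + Poisson); ``gba_strength`` is the probability that an interaction
    edge joins a label-sharing pair.
    """

    n_proteins: int = 500
    scheme: FunctionScheme | None = None
    category_weights: tuple[float, ...] | None = None
    mean_labels: float = 3.1
    n_profiles: int = 40
    label_noise: float = 0.1
    n_clusters: int = 25
    homology_fraction: float = 0.4
    similarity_base: tuple[float, float] = (50.0, 80.0)
    similarity_overlap_bonus: float = 15.0
    gba_strength: float = 0.9
    edges_per_protein: int = 8
    interaction_base: float = 300.0
    interaction_spread: float = 400.0
    orphan_fraction: float = 0.05
    sequence_length_range: tuple[int, int] = (80, 300)
    residue_tilt: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        for name in ("homology_fraction", "orphan_fraction", "gba_strength", "label_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.homology_fraction + self.orphan_fraction > 1.0:
            raise ValueError(
                "infeasible config: homology_fraction + orphan_fraction > 1"
            )
        if self.mean_labels < 1.0:
            raise ValueError("mean_labels must be >= 1")
        lo, hi = self.sequence_length_range
        if lo < 2 or hi < lo:
            raise ValueError(f"bad sequence_length_range {self.sequence_length_range}")


def label_sharing_rate(annotations) -> float:
    """Fraction of unordered protein pairs sharing at least one category."""
    sets = [frozenset(c) for c in annotations.values()]
    n = len(sets)
    if n < 2:
        raise ValueError("need at least 2 annotated proteins")
    cats = sorted({c for s in sets for c in s})
    row = {c: i for i, c in enumerate(cats)}
    d = np.zeros((len(cats), n), dtype=np.int64)
    for j, s in enumerate(sets):
        for c in s:
            d[row[c], j] = 1
    overlap = d.T @ d
    share = overlap > 0
    np.fill_diagonal(share, False)
    return float(share.sum()) / (n * (n - 1))


def generate_dataset(config: GeneratorConfig) -> Dataset:
    """Generate a full synthetic dataset (sequences, annotations, evidence).

    The returned :class:`~funcascade.io.Dataset` carries the ground-truth
    annotations in its ``annotations`` field; evaluation protocols mask them
    for held-out proteins.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    scheme = config.scheme or FunctionScheme.funcat24()
    k = scheme.size
    numbers = scheme.numbers
    weights = np.asarray(
        config.category_weights
        if config.category_weights is not None
        else _default_weights()[:k],
        dtype=float,
    )
    if weights.shape != (k,):
        raise ValueError(f"category_weights must have {k} entries")
    probs = weights / weights.sum()
    n = config.n_proteins
    ids = [f"syn{i:05d}" for i in range(n)]

    # label profiles (functional modules) and their popularity
    profiles: list[np.ndarray] = []
    for _ in range(config.n_profiles):
        size = int(min(1 + rng.poisson(config.mean_labels - 1.0), k))
        profiles.append(np.sort(rng.choice(numbers, size=size, replace=False, p=probs)))
    # popularity follows the member categories' weights, size-normalized so
    # that profile size does not bias the realized label-count mean
    popularity = np.array(
        [weights[[scheme.index(c) for c in prof]].mean() for prof in profiles]
    )
    popularity = popularity / popularity.sum()
    assignment = rng.choice(config.n_profiles, size=n, p=popularity)

    # homology clusters overwrite their members' profiles with a shared one
    n_clustered = round(config.homology_fraction * n)
    clustered = rng.choice(n, size=n_clustered, replace=False) if n_clustered else np.array([], dtype=int)
    cluster_of = {}
    if n_clustered:
        cluster_ids = rng.integers(0, config.n_clusters, size=n_clustered)
        cluster_profile = rng.choice(config.n_profiles, size=config.n_clusters, p=popularity)
        for prot, clu in zip(clustered, cluster_ids):
            cluster_of[int(prot)] = int(clu)
            assignment[prot] = cluster_profile[clu]

    # final label sets: profile labels, occasionally with one label swapped
    # for a random weighted category (count-preserving noise)
    labels: list[set[int]] = []
    for i in range(n):
        cats = set(int(c) for c in profiles[assignment[i]])
        if rng.random() < config.label_noise:
            new = int(rng.choice(numbers, p=probs))
            if new not in cats:
                cats.remove(int(rng.choice(sorted(cats))))
                cats.add(new)
        labels.append(cats)
    annotations = {pid: frozenset(cats) for pid, cats in zip(ids, labels)}

    # orphan proteins: no hits, no edges (drawn outside the clusters)
    unclustered = np.setdiff1d(np.arange(n), clustered)
    n_orphans = round(config.orphan_fraction * n)
    orphans = set(
        int(i) for i in rng.choice(unclustered, size=n_orphans, replace=False)
    ) if n_orphans else set()

    # similarity hits within clusters, score increasing with label overlap
    indicator = np.zeros((k, n), dtype=np.int64)
    for j, cats in enumerate(labels):
        for c in cats:
            indicator[scheme.index(c), j] = 1
    overlap = indicator.T @ indicator
    hits: list[tuple[str, str, float]] = []
    members_by_cluster: dict[int, list[int]] = {}
    for prot, clu in cluster_of.items():
        members_by_cluster.setdefault(clu, []).append(prot)
    lo, hi = config.similarity_base
    for clu in sorted(members_by_cluster):
        members = sorted(members_by_cluster[clu])
        for a_pos, a in enumerate(members):
            for b in members[a_pos + 1 :]:
                score = rng.uniform(lo, hi) + config.similarity_overlap_bonus * overlap[a, b]
                hits.append((ids[a], ids[b], float(score)))
                hits.append((ids[b], ids[a], float(score)))

    # Interaction edges.  gba_strength g is the probability that an edge
    # joins a label-sharing pair.  Edges mix three uniform pair pools —
    # same-module (functional-module co-members, which share labels by
    # construction), uniform random, and non-sharing — with the mixing rate
    # solved against the realized random-pair sharing rate rho so that
    # P(edge shares) = g exactly:
    #   g >= rho: same-module with prob (g-rho)/(1-rho), else uniform;
    #   g <  rho: non-sharing with prob 1-g/rho, else uniform.
    # Hence g=1 wires whole functional modules (perfect GBA), and g=rho
    # reproduces uniform random pairing in distribution (the null model).
    # Edge weights are independent of the labels so a null network carries
    # no annotation signal at all.
    share = overlap > 0
    np.fill_diagonal(share, False)
    edges: list[tuple[str, str, float]] = []
    eligible = np.array(sorted(set(range(n)) - orphans), dtype=int)
    if eligible.size >= 2:
        sub_share = share[np.ix_(eligible, eligible)]
        iu = np.triu_indices(eligible.size, k=1)
        pair_shares = sub_share[iu]
        same_module = (
            assignment[eligible][iu[0]] == assignment[eligible][iu[1]]
        ) & pair_shares
        all_pairs = np.arange(pair_shares.size)
        module_pairs = np.nonzero(same_module)[0]
        nonsharing_pairs = np.nonzero(~pair_shares)[0]
        rho = float(pair_shares.mean())
        g = config.gba_strength
        if g >= rho:
            q = (g - rho) / (1.0 - rho) if rho < 1.0 else 0.0
            informative, other = module_pairs, all_pairs
        else:
            q = 1.0 - g / rho
            informative, other = nonsharing_pairs, all_pairs
        n_edges = (config.edges_per_protein * eligible.size) // 2
        for _ in range(n_edges):
            pool = informative if (rng.random() < q and informative.size) else other
            p = int(pool[rng.integers(pool.size)])
            a = int(eligible[iu[0][p]])
            b = int(eligible[iu[1][p]])
            w = config.interaction_base + rng.uniform(0.0, config.interaction_spread)
            edges.append((ids[a], ids[b], float(w)))

    # sequences from label-dependent residue-usage tilts
    tilt = rng.normal(0.0, 1.0, size=(k, 20))
    alphabet = np.array(list(AMINO_ACIDS))
    lo_len, hi_len = config.sequence_length_range
    sequences: dict[str, str] = {}
    for i, pid in enumerate(ids):
        logits = config.residue_tilt * tilt[[scheme.index(c) for c in sorted(labels[i])]].sum(axis=0)
        p = np.exp(logits - logits.max())
        p = p / p.sum()
        length = int(rng.integers(lo_len, hi_len + 1))
        sequences[pid] = "".join(rng.choice(alphabet, size=length, p=p))

    return Dataset(
        sequences=sequences,
        annotations=annotations,
        similarity_hits=hits,
        interaction_edges=edges,
        id_map=None,
    )
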