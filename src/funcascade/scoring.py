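"""Evidence-weighted function scoring and the sequential cascade.

Three guilt-by-association voters turn per-reference evidence weights into a
per-category score vector by a weighted vote ``score_j = sum_i d[j,i] * w_i``
over annotated reference proteins:

* similarity: alignment bit scores ``s_i`` of the query's homologues,
* interaction: network combined scores ``t_i`` of the query's neighbours,
* PseAAC: cosine similarity between the query's and every reference's
  PseAAC descriptor (always defined when references exist).

The cascade tries them in that order and uses the first branch with any
evidence, so every query receives a ranked prediction whenever the reference
set is non-empty.  :class:`FunctionCascade` packages the cascade as a
scikit-learn-style estimator whose ``predict`` accepts an exclusion set, so
leave-one-out and k-fold protocols can hold proteins out without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .annotation import (
    BRANCH_INTERACTION,
    BRANCH_PSEAAC,
    BRANCH_SIMILARITY,
    AnnotationMatrix,
    FunctionScheme,
    RankedPrediction,
    ScoreVector,
    build_annotation_matrix,
    rank_functions,
)
from .io import Dataset
from .pseaac import DEFAULT_LAMBDA, DEFAULT_WEIGHT, PseAACEncoder, cosine_similarity


@dataclass
class EvidenceBundle:
    """All evidence available for one query protein.

    Absence of a key means absence of evidence: an empty ``similarity``
    mapping is the no-homologue condition, an empty ``interaction`` mapping
    the no-edge condition.
    """

    similarity: dict[str, float] = field(default_factory=dict)
    interaction: dict[str, float] = field(default_factory=dict)
    pseaac_query: np.ndarray | None = None
    pseaac_refs: dict[str, np.ndarray] = field(default_factory=dict)


def _weighted_vote(weights: dict[str, float], refs: AnnotationMatrix) -> np.ndarray:
    scores = np.zeros(refs.scheme.size)
    for pid, w in weights.items():
        if not np.isfinite(w) or w < 0:
            raise ValueError(f"evidence weight for {pid!r} must be finite and >= 0")
        try:
            col = refs.column_index[pid]
        except KeyError:
            raise KeyError(f"protein {pid!r} is not in the reference set") from None
        scores += refs.indicator[:, col] * w
    return scores


def score_by_similarity(bundle: EvidenceBundle, refs: AnnotationMatrix) -> ScoreVector | None:
    """Similarity-weighted vote; ``None`` signals the no-homologue condition."""
    if not bundle.similarity:
        return None
    return ScoreVector(_weighted_vote(bundle.similarity, refs), BRANCH_SIMILARITY, refs.scheme)


def score_by_interaction(bundle: EvidenceBundle, refs: AnnotationMatrix) -> ScoreVector | None:
    """Interaction-weighted vote; ``None`` signals the no-edge condition."""
    if not bundle.interaction:
        return None
    return ScoreVector(_weighted_vote(bundle.interaction, refs), BRANCH_INTERACTION, refs.scheme)


def score_by_pseaac(
    bundle: EvidenceBundle, refs: AnnotationMatrix, top_k: int | None = None
) -> ScoreVector:
    """PseAAC-cosine-weighted vote over the reference set.

    By default every reference contributes with weight equal to its cosine
    similarity to the query; ``top_k`` optionally restricts the vote to the
    k nearest references.
    """
    if not bundle.pseaac_refs:
        raise ValueError("PseAAC scoring requires a non-empty reference set")
    if bundle.pseaac_query is None:
        raise ValueError("PseAAC scoring requires a query feature vector")
    cosines = {
        pid: cosine_similarity(bundle.pseaac_query, vec)
        for pid, vec in bundle.pseaac_refs.items()
    }
    if top_k is not None and top_k < len(cosines):
        kept = sorted(cosines, key=lambda p: (-cosines[p], p))[:top_k]
        cosines = {p: cosines[p] for p in kept}
    return ScoreVector(_weighted_vote(cosines, refs), BRANCH_PSEAAC, refs.scheme)


def predict_combined(
    bundle: EvidenceBundle, refs: AnnotationMatrix, top_k: int | None = None
) -> RankedPrediction:
    """Run the sequential cascade: similarity, then interaction, then PseAAC."""
    if refs.n_proteins == 0:
        raise ValueError("cannot predict against an empty reference set")
    scores = score_by_similarity(bundle, refs)
    if scores is None:
        scores = score_by_interaction(bundle, refs)
    if scores is None:
        scores = score_by_pseaac(bundle, refs, top_k=top_k)
    return rank_functions(scores)


class FunctionCascade(BaseEstimator):
    """Sequential similarity / interaction / PseAAC function predictor.

    ``fit`` ingests a :class:`~funcascade.io.Dataset` (annotations, sequences
    and evidence tables) and precomputes the reference indicator matrix and
    PseAAC descriptors.  ``predict`` takes query protein IDs plus an optional
    ``exclude`` set that is removed from the reference universe for *all*
    branches — this single mechanism realises self-hit removal in
    leave-one-out and test-fold removal in k-fold cross-validation.

    Parameters
    ----------
    scheme:
        Function scheme; default the 24 FunCat top categories.
    lam, weight, properties, shared_denominator:
        PseAAC encoding parameters, see :class:`~funcascade.pseaac.PseAACEncoder`.
    top_k:
        Optional nearest-neighbour restriction of the PseAAC vote.

    Attributes
    ----------
    reference_ids_ : tuple[str, ...]
        Annotated proteins usable as references.
    annotation_ : AnnotationMatrix
        Indicator matrix over ``reference_ids_``.
    features_ : dict[str, numpy.ndarray]
        PseAAC descriptor per protein that has a sequence.
    """

    def __init__(
        self,
        scheme: FunctionScheme | None = None,
        lam: int = DEFAULT_LAMBDA,
        weight: float = DEFAULT_WEIGHT,
        properties=None,
        shared_denominator: bool = True,
        top_k: int | None = None,
    ):
        self.scheme = scheme
        self.lam = lam
        self.weight = weight
        self.properties = properties
        self.shared_denominator = shared_denominator
        self.top_k = top_k

    def fit(self, dataset: Dataset, reference_ids=None, features=None):
        """Index a dataset for prediction.

        Parameters
        ----------
        dataset:
            Sequences, annotations and evidence tables.
        reference_ids:
            Subset of annotated proteins to use as references (default all).
        features:
            Optional precomputed ``{id: PseAAC vector}`` cache; proteins not
            present are encoded from their sequence.
        """
        self.scheme_ = self.scheme or FunctionScheme.funcat24()
        if reference_ids is None:
            reference_ids = list(dataset.annotations)
        else:
            reference_ids = [p for p in reference_ids]
            missing = [p for p in reference_ids if p not in dataset.annotations]
            if missing:
                raise ValueError(f"reference proteins without annotations: {missing[:5]}")
        if not reference_ids:
            raise ValueError("reference set is empty")
        self.reference_ids_ = tuple(reference_ids)
        self.annotation_ = build_annotation_matrix(
            ((p, dataset.annotations[p]) for p in reference_ids), self.scheme_
        )
        self.encoder_ = PseAACEncoder(
            properties=self.properties,
            lam=self.lam,
            weight=self.weight,
            shared_denominator=self.shared_denominator,
        ).fit()
        if features is None:
            ids = list(dataset.sequences)
            matrix = self.encoder_.transform(dataset.sequences[p] for p in ids)
            features = {p: matrix[i] for i, p in enumerate(ids)}
        self.features_ = features
        self._dataset = dataset
        self._hits = dataset.hits_by_query()
        self._adjacency = dataset.adjacency()
        # unit-norm reference feature matrix for the vectorized cosine vote
        ref_vecs = []
        ref_ok = np.zeros(len(reference_ids), dtype=bool)
        dim = self.encoder_.n_features_out_
        for i, p in enumerate(reference_ids):
            v = features.get(p)
            if v is not None and np.linalg.norm(v) > 0:
                ref_vecs.append(v / np.linalg.norm(v))
                ref_ok[i] = True
            else:
                ref_vecs.append(np.zeros(dim))
        self._ref_unit = np.vstack(ref_vecs)
        self._ref_has_features = ref_ok
        return self

    def _active_mask(self, query_id: str, exclude) -> np.ndarray:
        mask = np.ones(len(self.reference_ids_), dtype=bool)
        drop = {query_id}
        if exclude:
            drop |= set(exclude)
        idx = self.annotation_.column_index
        for pid in drop:
            if pid in idx:
                mask[idx[pid]] = False
        return mask

    def _pseaac_scores(self, query_id: str, mask: np.ndarray) -> ScoreVector:
        v = self.features_.get(query_id)
        if v is None:
            seq = self._dataset.sequences.get(query_id)
            if seq is None:
                raise KeyError(f"no sequence available for query {query_id!r}")
            v = self.encoder_.transform([seq])[0]
            self.features_[query_id] = v
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError(f"query {query_id!r} has a zero PseAAC vector")
        active = mask & self._ref_has_features
        if not active.any():
            raise ValueError("no reference protein has PseAAC features")
        cosines = self._ref_unit[active] @ (v / norm)
        if self.top_k is not None and self.top_k < cosines.size:
            cut = np.sort(cosines)[-self.top_k]
            keep = cosines >= cut
            cosines = cosines * keep
        scores = self.annotation_.indicator[:, active].astype(float) @ cosines
        return ScoreVector(scores, BRANCH_PSEAAC, self.scheme_)

    def predict_one(self, query_id: str, exclude=None) -> RankedPrediction:
        """Cascade prediction for one query; see class docstring for
        exclusion semantics."""
        if not hasattr(self, "annotation_"):
            raise RuntimeError("FunctionCascade is not fitted")
        mask = self._active_mask(query_id, exclude)
        if not mask.any():
            raise ValueError("reference set is empty after exclusions")
        idx = self.annotation_.column_index

        sim = {
            r: s
            for r, s in self._hits.get(query_id, {}).items()
            if r in idx and mask[idx[r]]
        }
        if sim:
            return rank_functions(
                ScoreVector(_weighted_vote(sim, self.annotation_), BRANCH_SIMILARITY, self.scheme_)
            )
        inter = {
            r: w
            for r, w in self._adjacency.get(query_id, {}).items()
            if r in idx and mask[idx[r]]
        }
        if inter:
            return rank_functions(
                ScoreVector(_weighted_vote(inter, self.annotation_), BRANCH_INTERACTION, self.scheme_)
            )
        return rank_functions(self._pseaac_scores(query_id, mask))

    def predict(self, query_ids, exclude=None) -> list[RankedPrediction]:
        """Cascade predictions for an iterable of query IDs."""
        return [self.predict_one(q, exclude=exclude) for q in query_ids]
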