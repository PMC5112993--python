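"""Multi-label function annotations and ranked predictions.

Functions follow the FunCat top-level scheme by default: 24 broad categories
(metabolism, energy, transcription, ...).  A protein may carry several
categories at once, so annotations are held as a K x n binary indicator
matrix D with ``d[j, i] = 1`` iff protein i has function j.  A predictor
produces a K-dimensional score vector; sorting it descending yields the
"order-k" prediction sequence: the top-scoring category is the 1st-order
prediction, the next the 2nd-order, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: FunCat top-level categories: (number, label, protein count in the mouse
#: reference annotation).  The counts double as the default skew of the
#: synthetic generator.
FUNCAT_CATEGORIES: tuple[tuple[int, str, int], ...] = (
    (1, "METABOLISM", 2401),
    (2, "ENERGY", 522),
    (3, "CELL CYCLE AND DNA PROCESSING", 971),
    (4, "TRANSCRIPTION", 1921),
    (5, "PROTEIN SYNTHESIS", 399),
    (6, "PROTEIN FATE (folding modification destination)", 2187),
    (7, "PROTEIN WITH BINDING FUNCTION OR COFACTOR REQUIREMENT (structural or catalytic)", 7330),
    (8, "REGULATION OF METABOLISM AND PROTEIN FUNCTION", 972),
    (9, "CELLULAR TRANSPORT TRANSPORT FACILITIES AND TRANSPORT ROUTES", 2078),
    (10, "CELLULAR COMMUNICATION/SIGNAL TRANSDUCTION MECHANISM", 3143),
    (11, "CELL RESCUE DEFENSE AND VIRULENCE", 656),
    (12, "INTERACTION WITH THE ENVIRONMENT", 1212),
    (13, "SYSTEMIC INTERACTION WITH THE ENVIRONMENT", 1454),
    (14, "TRANSPOSABLE ELEMENTS VIRAL AND PLASMID PROTEINS", 9),
    (15, "CELL FATE", 1180),
    (16, "DEVELOPMENT (Systemic)", 939),
    (17, "BIOGENESIS OF CELLULAR COMPONENTS", 769),
    (18, "CELL TYPE DIFFERENTIATION", 317),
    (19, "TISSUE DIFFERENTIATION", 313),
    (20, "ORGAN DIFFERENTIATION", 491),
    (21, "SUBCELLULAR LOCALIZATION", 8467),
    (22, "CELL TYPE LOCALIZATION", 232),
    (23, "TISSUE LOCALIZATION", 261),
    (24, "ORGAN LOCALIZATION", 542),
)

#: Score-vector provenance labels (cascade branches).
BRANCH_SIMILARITY = "similarity"
BRANCH_INTERACTION = "interaction"
BRANCH_PSEAAC = "pseaac"


@dataclass(frozen=True)
class FunctionScheme:
    """An ordered set of function categories ``(number, label)``."""

    categories: tuple[tuple[int, str], ...]

    def __post_init__(self):
        numbers = [n for n, _ in self.categories]
        if len(set(numbers)) != len(numbers):
            raise ValueError("category numbers must be unique")
        if len(numbers) < 2:
            raise ValueError("a scheme needs at least 2 categories")

    @classmethod
    def funcat24(cls) -> "FunctionScheme":
        return cls(tuple((n, label) for n, label, _ in FUNCAT_CATEGORIES))

    @classmethod
    def generic(cls, k: int) -> "FunctionScheme":
        """A bare numeric scheme 1..k (handy for small tests)."""
        return cls(tuple((i, f"category {i}") for i in range(1, k + 1)))

    @property
    def size(self) -> int:
        return len(self.categories)

    @property
    def numbers(self) -> np.ndarray:
        return np.array([n for n, _ in self.categories], dtype=int)

    def index(self, number: int) -> int:
        """Row index of a category number."""
        try:
            return self._index[number]
        except AttributeError:
            object.__setattr__(
                self, "_index", {n: i for i, (n, _) in enumerate(self.categories)}
            )
            return self._index[number]


@dataclass
class AnnotationMatrix:
    """K x n binary function-indicator matrix over reference proteins."""

    scheme: FunctionScheme
    protein_ids: tuple[str, ...]
    indicator: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.indicator = np.asarray(self.indicator)
        if self.indicator.shape != (self.scheme.size, len(self.protein_ids)):
            raise ValueError(
                f"indicator shape {self.indicator.shape} does not match "
                f"({self.scheme.size}, {len(self.protein_ids)})"
            )
        if not np.isin(self.indicator, (0, 1)).all():
            raise ValueError("indicator entries must be 0 or 1")
        self.column_index = {p: i for i, p in enumerate(self.protein_ids)}

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def categories_of(self, protein_id: str) -> frozenset[int]:
        """Read back a protein's category-number set."""
        col = self.indicator[:, self.column_index[protein_id]]
        return frozenset(int(n) for n in self.scheme.numbers[col.astype(bool)])


def build_annotation_matrix(
    annotations,
    scheme: FunctionScheme | None = None,
    require_annotated: bool = True,
) -> AnnotationMatrix:
    """Build the indicator matrix from ``(protein_id, {category numbers})``.

    Reference proteins must carry at least one category unless
    ``require_annotated=False`` (queries may legitimately be unannotated).
    """
    scheme = scheme or FunctionScheme.funcat24()
    items = list(annotations)
    ids = [pid for pid, _ in items]
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for pid in ids:
            if pid in seen:
                dup = pid
                break
            seen.add(pid)
        raise ValueError(f"duplicate protein ID {dup!r}")
    matrix = np.zeros((scheme.size, len(items)), dtype=np.uint8)
    for col, (pid, cats) in enumerate(items):
        if require_annotated and not cats:
            raise ValueError(f"protein {pid!r} has no categories")
        for c in cats:
            try:
                row = scheme.index(int(c))
            except KeyError:
                raise ValueError(
                    f"protein {pid!r}: category {c} is not in the scheme"
                ) from None
            matrix[row, col] = 1
    return AnnotationMatrix(scheme=scheme, protein_ids=tuple(ids), indicator=matrix)


@dataclass
class ScoreVector:
    """Per-category function scores produced by one evidence branch."""

    scores: np.ndarray
    source: str
    scheme: FunctionScheme

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (self.scheme.size,):
            raise ValueError(
                f"expected {self.scheme.size} scores, got {self.scores.shape}"
            )


@dataclass
class RankedPrediction:
    """Categories sorted by descending score: ``order[0]`` is the 1st-order
    prediction, ``order[k-1]`` the k-th-order prediction."""

    order: np.ndarray
    scores: ScoreVector
    branch: str

    def order_k(self, k: int) -> int:
        """Category number of the k-th-order prediction (1-based)."""
        return int(self.order[k - 1])


def rank_functions(scores: ScoreVector) -> RankedPrediction:
    """Sort categories by descending score into an order-k prediction.

    Ties are broken by ascending category number, which makes the ranking
    deterministic across runs and platforms.
    """
    values = scores.scores
    if not np.all(np.isfinite(values)):
        raise ValueError("scores must be finite")
    numbers = scores.scheme.numbers
    idx = np.lexsort((numbers, -values))
    return RankedPrediction(order=numbers[idx], scores=scores, branch=scores.source)
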