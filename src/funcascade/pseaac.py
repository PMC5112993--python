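"""Pseudo amino acid composition (PseAAC) sequence features.

PseAAC maps a protein sequence onto a fixed-length numeric vector that
combines the 20 amino-acid occurrence frequencies with lag-``i`` correlation
factors of physicochemical property profiles, so that sequence-order
information survives the loss of alignment.  With the packaged five property
scales (polarity, secondary structure, molecular volume, codon diversity,
electrostatic charge) and the default lag depth ``lam=50`` the descriptor has
20 + 5*50 = 270 dimensions.

The property scales shipped with the package are published factor scores that
already have zero mean and unit mean square over the 20 standard residues;
:func:`normalize_property` is applied only to user-supplied raw scales.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

#: The 20 standard amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Property scales packaged with the toolkit, in canonical order.
DEFAULT_PROPERTIES = (
    "polarity",
    "secondary structure",
    "molecular volume",
    "codon diversity",
    "electrostatic charge",
)

DEFAULT_LAMBDA = 50
DEFAULT_WEIGHT = 0.15


class DegeneratePropertyError(ValueError):
    """All property values identical: the normalization denominator is zero."""


class MalformedTableError(ValueError):
    """A property table does not define exactly the 20 standard residues."""


class SequenceTooShortError(ValueError):
    """The sequence has fewer than two residues usable for correlations."""


class ZeroVectorError(ValueError):
    """Cosine similarity is undefined for an all-zero vector."""


@dataclass(frozen=True)
class PropertyTable:
    """One physicochemical scale ``L(X)`` over the 20 standard amino acids.

    Parameters
    ----------
    name:
        Human-readable scale name.
    values:
        Mapping from each one-letter amino-acid code to its property value.
    normalized:
        True once the scale has been centred to mean 0 / mean square 1.
    """

    name: str
    values: dict[str, float] = field(repr=False)
    normalized: bool = False

    def __post_init__(self) -> None:
        if set(self.values) != set(AMINO_ACIDS):
            missing = sorted(set(AMINO_ACIDS) - set(self.values))
            extra = sorted(set(self.values) - set(AMINO_ACIDS))
            raise MalformedTableError(
                f"property table {self.name!r} must define exactly the 20 "
                f"standard residues (missing {missing}, unexpected {extra})"
            )
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise MalformedTableError(
                f"property table {self.name!r} contains non-finite values"
            )

    def as_array(self) -> np.ndarray:
        """Values ordered as :data:`AMINO_ACIDS`."""
        return np.array([self.values[a] for a in AMINO_ACIDS], dtype=float)


def normalize_property(raw: PropertyTable) -> PropertyTable:
    """Centre a raw scale to mean 0 and mean square 1 over the 20 residues.

    ``F(X) = (L(X) - mean L) / sqrt(mean (L - mean L)^2)`` with the mean taken
    over the 20 standard amino acids (population convention, divisor 20).
    Idempotent on already-normalized tables up to floating point.
    """
    arr = raw.as_array()
    centred = arr - arr.mean()
    scale = np.sqrt(np.mean(centred**2))
    if scale == 0.0:
        raise DegeneratePropertyError(
            f"property {raw.name!r} has identical values for all residues"
        )
    out = centred / scale
    return replace(raw, values=dict(zip(AMINO_ACIDS, out)), normalized=True)


def load_property_tables(names: tuple[str, ...] | None = None) -> list[PropertyTable]:
    """Load packaged property scales (the five factor-score columns).

    The packaged values are published factor scores and are used as-is, i.e.
    they are flagged normalized without re-applying the centring step.
    """
    text = (
        importlib.resources.files("funcascade")
        .joinpath("data/property_factors.tsv")
        .read_text()
    )
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")[1:]
    columns: dict[str, dict[str, float]] = {name: {} for name in header}
    for ln in lines[1:]:
        fields = ln.split("\t")
        aa = fields[0]
        for name, value in zip(header, fields[1:]):
            columns[name][aa] = float(value)
    wanted = names if names is not None else tuple(header)
    tables = []
    for name in wanted:
        if name not in columns:
            raise KeyError(
                f"unknown packaged property {name!r}; available: {header}"
            )
        tables.append(PropertyTable(name=name, values=columns[name], normalized=True))
    return tables


def read_property_table(path, name: str = "user", normalized: bool = False) -> PropertyTable:
    """Read a user scale from two-column ``letter<TAB-or-space>value`` text."""
    values: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise MalformedTableError(
                    f"{path}:{lineno}: expected 'letter value', got {line!r}"
                )
            letter = fields[0].upper()
            if letter in values:
                raise MalformedTableError(f"{path}:{lineno}: duplicate residue {letter}")
            values[letter] = float(fields[1])
    return PropertyTable(name=name, values=values, normalized=normalized)


# ---------------------------------------------------------------------------
# encoding primitives


def _profile(sequence: str, prop: PropertyTable) -> np.ndarray:
    """Per-residue property values, NaN where the residue is non-standard.

    Non-standard letters (B, J, O, U, X, Z, ...) are treated as sequence
    gaps: they carry no value and break correlation windows.
    """
    lut = np.full(128, np.nan)
    for aa in AMINO_ACIDS:
        lut[ord(aa)] = prop.values[aa]
    codes = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    return lut[codes]


def _correlation_from_profile(profile: np.ndarray, lam: int) -> np.ndarray:
    """Lag-1..lam mean squared differences of a (possibly gapped) profile.

    A pair at lag ``i`` contributes only when both residues are standard and
    no gap lies between them; lags with no valid pair yield 0 (this also
    implements zero-padding when ``lam`` exceeds the sequence length - 1).
    """
    gaps = np.isnan(profile)
    segment = np.cumsum(gaps)  # constant within a gap-free stretch
    out = np.zeros(lam)
    n = profile.size
    for i in range(1, min(lam, max(n - 1, 0)) + 1):
        a, b = profile[:-i], profile[i:]
        valid = ~np.isnan(a) & ~np.isnan(b) & (segment[:-i] == segment[i:])
        if valid.any():
            d = a[valid] - b[valid]
            out[i - 1] = np.mean(d * d)
    return out


def correlation_factors(sequence: str, prop: PropertyTable, lam: int) -> np.ndarray:
    """Correlation factors ``C_1..C_lam`` of a sequence under one property.

    ``C_i = (1/(N-i)) * sum_k (F(X_k) - F(X_{k+i}))^2``; for ``lam > N-1``
    the remaining entries are zero so the output always has length ``lam``.
    """
    if lam < 1:
        raise ValueError(f"lam must be >= 1, got {lam}")
    n_std = sum(1 for c in sequence.upper() if c in AMINO_ACIDS)
    if n_std < 2:
        raise SequenceTooShortError(
            f"need at least 2 standard residues for correlation factors, got {n_std}"
        )
    return _correlation_from_profile(_profile(sequence, prop), lam)


def pseaac_encode(
    sequence: str,
    props: list[PropertyTable] | None = None,
    lam: int = DEFAULT_LAMBDA,
    weight: float = DEFAULT_WEIGHT,
    shared_denominator: bool = True,
) -> np.ndarray:
    """Encode one sequence into a ``20 + m*lam`` PseAAC vector.

    The first 20 entries are amino-acid frequencies ``f_i`` and, for each of
    the ``m`` property scales, ``lam`` correlation entries ``weight * C_i``,
    all divided by a common denominator ``sum f + weight * S``.  Under the
    default shared-denominator convention ``S`` sums the correlation factors
    of *all* properties, so the full vector sums to exactly 1; with
    ``shared_denominator=False`` each property block is normalized by its own
    Chou denominator (and the composition block by the first property's).
    """
    if props is None:
        props = load_property_tables()
    if not props:
        raise ValueError("props must be non-empty")
    if weight <= 0:
        raise ValueError(f"weight must be positive, got {weight}")
    if lam < 1:
        raise ValueError(f"lam must be >= 1, got {lam}")
    seq = sequence.upper()
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    aa_codes = np.frombuffer(AMINO_ACIDS.encode("ascii"), dtype=np.uint8)
    counts = np.array([(codes == c).sum() for c in aa_codes], dtype=float)
    n_std = counts.sum()
    if n_std == 0:
        raise ValueError("sequence contains no standard residues")
    freqs = counts / n_std

    if n_std >= 2:
        corr = [_correlation_from_profile(_profile(seq, p), lam) for p in props]
    else:
        corr = [np.zeros(lam) for _ in props]

    if shared_denominator:
        denom = 1.0 + weight * sum(c.sum() for c in corr)
        blocks = [freqs / denom] + [weight * c / denom for c in corr]
    else:
        denoms = [1.0 + weight * c.sum() for c in corr]
        blocks = [freqs / denoms[0]] + [
            weight * c / d for c, d in zip(corr, denoms)
        ]
    return np.concatenate(blocks)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two feature vectors, in [0, 1] for
    nonnegative vectors; symmetric and invariant to positive rescaling."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ZeroVectorError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


class PseAACEncoder(TransformerMixin, BaseEstimator):
    """Transform protein sequences into PseAAC feature vectors.

    Parameters
    ----------
    properties:
        Property scales to use; either a tuple of packaged scale names or a
        list of :class:`PropertyTable`.  ``None`` selects the five packaged
        scales.
    lam:
        Correlation depth (entries per property); default 50.
    weight:
        Sequence-order weight applied to the correlation entries; default 0.15.
    shared_denominator:
        Normalization convention, see :func:`pseaac_encode`.

    Attributes
    ----------
    property_tables_ : list[PropertyTable]
        Resolved scales after :meth:`fit`.
    n_features_out_ : int
        Output dimensionality ``20 + m * lam`` (270 with defaults).
    """

    def __init__(
        self,
        properties=None,
        lam: int = DEFAULT_LAMBDA,
        weight: float = DEFAULT_WEIGHT,
        shared_denominator: bool = True,
    ):
        self.properties = properties
        self.lam = lam
        self.weight = weight
        self.shared_denominator = shared_denominator

    def _resolve_tables(self) -> list[PropertyTable]:
        props = self.properties
        if props is None:
            return load_property_tables()
        if all(isinstance(p, PropertyTable) for p in props):
            return list(props)
        return load_property_tables(tuple(props))

    def fit(self, X=None, y=None):
        if self.lam < 1:
            raise ValueError(f"lam must be >= 1, got {self.lam}")
        if self.weight <= 0:
            raise ValueError(f"weight must be positive, got {self.weight}")
        self.property_tables_ = self._resolve_tables()
        self.n_features_out_ = 20 + len(self.property_tables_) * self.lam
        return self

    def transform(self, X) -> np.ndarray:
        """Encode an iterable of sequences into an ``(n, 20 + m*lam)`` array."""
        if not hasattr(self, "property_tables_"):
            self.fit()
        rows = [
            pseaac_encode(
                seq,
                self.property_tables_,
                lam=self.lam,
                weight=self.weight,
                shared_denominator=self.shared_denominator,
            )
            for seq in X
        ]
        if not rows:
            return np.empty((0, self.n_features_out_))
        return np.vstack(rows)
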