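"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain double loops over the defining sums,
deliberately sharing no code with the package internals.
"""

from collections import Counter

from funcascade import AMINO_ACIDS


def naive_correlation(seq: str, values: dict[str, float], lam: int) -> list[float]:
    profile = [values[c] for c in seq]
    n = len(profile)
    out = []
    for i in range(1, lam + 1):
        if i <= n - 1:
            total = sum((profile[k] - profile[k + i]) ** 2 for k in range(n - i))
            out.append(total / (n - i))
        else:
            out.append(0.0)
    return out


def naive_pseaac(seq: str, props, lam: int, weight: float) -> list[float]:
    counts = Counter(seq)
    n = len(seq)
    freqs = [counts.get(a, 0) / n for a in AMINO_ACIDS]
    corr = [naive_correlation(seq, p.values, lam) for p in props]
    denom = sum(freqs) + weight * sum(sum(c) for c in corr)
    vec = [f / denom for f in freqs]
    for c in corr:
        vec.extend(weight * x / denom for x in c)
    return vec


def naive_cosine(a, b) -> float:
    dot = sum(x * y for x, y in zip(a, b))
    na = sum(x * x for x in a) ** 0.5
    nb = sum(y * y for y in b) ** 0.5
    return dot / (na * nb)


def naive_vote(weights: dict[str, float], annotations: dict[str, set], numbers) -> list[float]:
    return [
        sum(w for pid, w in weights.items() if c in annotations[pid])
        for c in numbers
    ]
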