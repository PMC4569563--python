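"""Independent, definition-level reimplementations used only as test oracles.

Deliberately naive: plain-Python arithmetic, no numpy vectorisation, no code
shared with the package, so agreement is meaningful.
"""

import math


def _mean(xs):
    return sum(xs) / len(xs)


def _sd(xs, sample=True):
    m = _mean(xs)
    denom = len(xs) - 1 if sample else len(xs)
    if denom == 0:
        return 0.0
    return math.sqrt(sum((x - m) ** 2 for x in xs) / denom)


def select_significant_oracle(series: dict[str, list[float]], sample_sd: bool = True) -> set[str]:
    """Direct transcription of the two selection rules.

    A gene is selected when its time-mean is at least the cross-gene
    mean-plus-sd of time-means, or its (nonzero) time-sd is at least the
    cross-gene mean-plus-sd of time-sds.
    """
    means = {g: _mean(xs) for g, xs in series.items()}
    sds = {g: _sd(xs, sample_sd) for g, xs in series.items()}
    t1 = _mean(list(means.values())) + _sd(list(means.values()), sample_sd)
    t2 = _mean(list(sds.values())) + _sd(list(sds.values()), sample_sd)
    out = set()
    for g in series:
        if means[g] >= t1:
            out.add(g)
        elif sds[g] > 0 and sds[g] >= t2:
            out.add(g)
    return out


def pearson_oracle(x, y) -> float:
    """Product-moment correlation straight from the definition."""
    mx, my = _mean(x), _mean(y)
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
       "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D", "N": "N"}


def revcomp_oracle(s: str) -> str:
    return "".join(_RC[c] for c in reversed(s))


def scan_oracle(sequence: str, consensus: str) -> list[tuple[int, str]]:
    """Sliding-window IUPAC match on both strands.

    Returns (start index in sequence, strand) tuples; an N in the sequence
    matches nothing.
    """
    hits = []
    seq = sequence.upper()
    for strand, cons in (("+", consensus.upper()), ("-", revcomp_oracle(consensus.upper()))):
        m = len(cons)
        for i in range(len(seq) - m + 1):
            window = seq[i : i + m]
            if all(base in IUPAC_SETS[c] for base, c in zip(window, cons)):
                hits.append((i, strand))
    return sorted(hits)
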