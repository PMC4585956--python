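"""Fickett TESTCODE statistic.

Combines, for each base, a position parameter (3-periodic asymmetry,
``max(count_phase0..2) / (min + 1)``) and a content parameter (base
fraction) through the published lookup tables and weights of Fickett
(1982). Higher values indicate protein-coding character. The statistic is
computed over the full transcript sequence; bases other than A/C/G/T are
ignored.
"""

from __future__ import annotations

_BASES = "ACGT"

# Probability-of-coding lookup tables, indexed by descending parameter bins.
_POSITION_PARAM = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)
_POSITION_PROB = {
    "A": (0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22),
    "C": (0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23),
    "G": (0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08),
    "T": (0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09),
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}

_CONTENT_PARAM = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0)
_CONTENT_PROB = {
    "A": (0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21),
    "C": (0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31),
    "G": (0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29),
    "T": (0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58),
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}


class UndefinedScoreError(ValueError):
    """Raised when the sequence contains no A/C/G/T bases."""


def _lookup(value: float, params, probs) -> float:
    for threshold, prob in zip(params, probs):
        if value >= threshold:
            return prob
    return probs[-1]


def fickett_score(sequence: str) -> float:
    """TESTCODE value of ``sequence`` (deterministic; larger = more coding-like)."""
    if len(sequence) < 6:
        raise ValueError("Fickett TESTCODE needs a sequence of length >= 6")
    seq = sequence.upper()
    phase_counts = {b: [0, 0, 0] for b in _BASES}
    for i, ch in enumerate(seq):
        if ch in phase_counts:
            phase_counts[ch][i % 3] += 1
    total = sum(sum(v) for v in phase_counts.values())
    if total == 0:
        raise UndefinedScoreError("sequence has no unambiguous A/C/G/T bases")
    score = 0.0
    for b in _BASES:
        c0, c1, c2 = phase_counts[b]
        position_param = max(c0, c1, c2) / (min(c0, c1, c2) + 1)
        content_param = (c0 + c1 + c2) / total
        score += _lookup(position_param, _POSITION_PARAM, _POSITION_PROB[b]) * _POSITION_WEIGHT[b]
        score += _lookup(content_param, _CONTENT_PARAM, _CONTENT_PROB[b]) * _CONTENT_WEIGHT[b]
    return score
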