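"""Semantic-pattern and dependency-graph features for CPI candidates.

All positional features are computed on the masked token sequence, in which
every tagged entity is exactly one token.  ``e1`` denotes the first-occurring
focal entity by token position and ``e2`` the second (the chemical/protein
order varies between sentences).  The feature set:

semantic pattern (tokens only)
    ``senlen`` sentence length in tokens; ``pos_e1``/``pos_e2``/``pos_iw``
    tokens before the element; ``n_entities`` tagged entities other than the
    focal pair; ``significant`` presence of "significant*" within three
    tokens before e1 or after e2; ``is_bracket`` e1 or e2 inside brackets;
    ``is_substrate`` presence of product/pathway/generate/synthesis-type
    words in the same windows; ``is_adjacent`` e1 and e2 next to each other;
    ``negation``/``conjunction`` presence of negative words or conjunctions
    in the token span covered by the candidate.

dependency graph
    ``steps_sp1``/``steps_sp2``/``steps_sp3`` edge counts of the shortest
    dependency paths e1-iw, iw-e2 and e1-e2; ``dist_sp*_words`` the same
    paths as word counts; ``sp_type`` one-hot topology class of the triple;
    one-hot presence of each typed dependency on each SDP (vocabulary frozen
    at fit time); ``appos_sp3`` appositive dependency on the e1-e2 path (a
    strong no-interaction signal); ``no_path`` disconnected-parse flag with
    all step features at the sentence-length sentinel.

The triplet track additionally carries the dictionary-mapped CPR group of
the interaction word as a categorical (``iw_cpr=<k>``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cpimine.candidates import InteractionMatch, MaskedSentence
from cpimine.depgraph import DepGraph, path_labels, shortest_path, sp_type

_BRACKET_OPEN = {"(", "[", "{"}
_BRACKET_CLOSE = {")", "]", "}"}

SP_TYPES = (-1, 0, 1, 2, 3, 4, 5, 6, 7)


@dataclass(frozen=True)
class FeatureConfig:
    """Window sizes and word lists behind the semantic-pattern features."""

    window: int = 3
    negation_words: frozenset[str] = frozenset(
        {"not", "no", "none", "neither", "nor", "cannot", "incapable",
         "unable", "fail", "fails", "failed", "lack", "lacks", "without"}
    )
    conjunction_words: frozenset[str] = frozenset(
        {"although", "therefore", "whereas", "however", "but", "while",
         "though", "moreover", "nevertheless", "yet"}
    )
    #: case-insensitive prefixes; covers product/production, pathway,
    #: generate/generated, synthetic/synthesis
    substrate_stems: tuple[str, ...] = ("product", "pathway", "generat", "synthe")
    significant_stems: tuple[str, ...] = ("significant",)


DEFAULT_CONFIG = FeatureConfig()


def _focal_order(masked: MaskedSentence) -> tuple[int, int]:
    """(e1, e2) token indices: e1 is the first-occurring focal entity."""
    a, b = masked.chem_index, masked.prot_index
    return (a, b) if a < b else (b, a)


def _window_hit(tokens: list[str], e1: int, e2: int, stems: tuple[str, ...], w: int) -> int:
    lo = [t.lower() for t in tokens]
    window = lo[max(0, e1 - w) : e1] + lo[e2 + 1 : e2 + 1 + w]
    return int(any(t.startswith(stems) for t in window))


def _in_brackets(tokens: list[str], idx: int) -> bool:
    depth = 0
    for t in tokens[:idx]:
        if t in _BRACKET_OPEN:
            depth += 1
        elif t in _BRACKET_CLOSE:
            depth = max(0, depth - 1)
    return depth > 0


def pair_semantic_features(
    masked: MaskedSentence, cfg: FeatureConfig = DEFAULT_CONFIG
) -> dict[str, float]:
    """Token-level semantic-pattern features of a CPI pair."""
    tokens = masked.tokens
    e1, e2 = _focal_order(masked)
    region = [t.lower() for t in tokens[e1 : e2 + 1]]
    return {
        "senlen": float(len(tokens)),
        "pos_e1": float(e1),
        "pos_e2": float(e2),
        "n_entities": float(len(masked.cpt_indices)),
        "significant": float(_window_hit(tokens, e1, e2, cfg.significant_stems, cfg.window)),
        "is_bracket": float(_in_brackets(tokens, e1) or _in_brackets(tokens, e2)),
        "is_substrate": float(_window_hit(tokens, e1, e2, cfg.substrate_stems, cfg.window)),
        "is_adjacent": float(e2 - e1 == 1),
        "negation": float(any(t in cfg.negation_words for t in region)),
        "conjunction": float(any(t in cfg.conjunction_words for t in region)),
    }


def triplet_semantic_features(
    masked: MaskedSentence, match: InteractionMatch, cfg: FeatureConfig = DEFAULT_CONFIG
) -> dict[str, float]:
    """Pair features plus interaction-word position, CPR category and the
    candidate region extended to cover the interaction word."""
    feats = pair_semantic_features(masked, cfg)
    e1, e2 = _focal_order(masked)
    iw = match.token_index
    lo_r, hi_r = min(e1, iw), max(e2, iw)
    region = [t.lower() for t in masked.tokens[lo_r : hi_r + 1]]
    feats["negation"] = float(any(t in cfg.negation_words for t in region))
    feats["conjunction"] = float(any(t in cfg.conjunction_words for t in region))
    feats["pos_iw"] = float(iw)
    feats[f"iw_cpr={match.entry.mapped_cpr}"] = 1.0
    return feats


def sdp_features(
    graph: DepGraph,
    masked: MaskedSentence,
    match: InteractionMatch | None = None,
) -> dict[str, float]:
    """Shortest-dependency-path features over the masked sentence's parse.

    For pairs: the e1-e2 path (``sp3``).  For triplets additionally the
    e1-iw (``sp1``) and iw-e2 (``sp2``) paths and the ``sp_type`` one-hot.
    Disconnected parses take the sentence-length sentinel plus ``no_path``.
    """
    e1, e2 = _focal_order(masked)
    sentinel = float(len(masked.tokens))
    feats: dict[str, float] = {}

    def emit(tag: str, a: int, b: int) -> None:
        p = shortest_path(graph, a, b)
        if p is None:
            feats[f"steps_{tag}"] = sentinel
            feats[f"dist_{tag}_words"] = sentinel
            feats["no_path"] = 1.0
            return
        feats[f"steps_{tag}"] = float(p.length)
        feats[f"dist_{tag}_words"] = float(p.n_words)
        for lab in path_labels(p):
            feats[f"dep_{tag}={lab}"] = 1.0
        if tag == "sp3":
            feats["appos_sp3"] = float(any(l.startswith("appos") for l in p.labels))

    feats["no_path"] = 0.0
    feats["appos_sp3"] = 0.0
    emit("sp3", e1, e2)
    if match is not None:
        iw = match.token_index
        emit("sp1", e1, iw)
        emit("sp2", iw, e2)
        feats[f"sp_type={sp_type(graph, e1, iw, e2)}"] = 1.0
    return feats


def candidate_features(
    masked: MaskedSentence,
    graph: DepGraph | None,
    match: InteractionMatch | None = None,
    cfg: FeatureConfig = DEFAULT_CONFIG,
) -> dict[str, float]:
    """Full feature dictionary for one pair (match=None) or triplet."""
    if match is None:
        feats = pair_semantic_features(masked, cfg)
    else:
        feats = triplet_semantic_features(masked, match, cfg)
    if graph is not None:
        feats.update(sdp_features(graph, masked, match))
    return feats


# ---------------------------------------------------------------------------
# Matrix assembly
# ---------------------------------------------------------------------------

class RegistryMismatchError(ValueError):
    """A predict-time row carries a non-categorical feature unknown at fit time."""


@dataclass
class FeatureMatrix:
    """Named-column numeric matrix over candidates."""

    columns: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValueError("matrix shape disagrees with column registry")
        if self.values.size and not np.isfinite(self.values).all():
            raise ValueError("feature values must be finite")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns)

    def hstack(self, other: "FeatureMatrix") -> "FeatureMatrix":
        if self.n_rows != other.n_rows:
            raise ValueError("row counts differ")
        return FeatureMatrix(self.columns + other.columns,
                             np.hstack([self.values, other.values]))


def _is_categorical(name: str) -> bool:
    return "=" in name


def encode_matrix(
    rows: list[dict[str, float]],
    *,
    fit: bool = False,
    registry: list[str] | None = None,
) -> FeatureMatrix:
    """Assemble feature dictionaries into a :class:`FeatureMatrix`.

    With ``fit=True`` the column registry is learned from the rows (sorted
    names, deterministic).  At predict time, rows are projected onto the
    given registry: unseen categorical values (``name=value`` columns) map
    to all-zero one-hots; an unknown non-categorical feature is an error.
    """
    if fit:
        names = sorted({k for r in rows for k in r})
        registry = names
    elif registry is None:
        raise ValueError("predict-time encoding requires a registry")
    else:
        known = set(registry)
        for r in rows:
            for k in r:
                if k not in known and not _is_categorical(k):
                    raise RegistryMismatchError(f"unknown feature {k!r} at predict time")
    col_idx = {c: j for j, c in enumerate(registry)}
    values = np.zeros((len(rows), len(registry)), dtype=float)
    for i, r in enumerate(rows):
        for k, v in r.items():
            j = col_idx.get(k)
            if j is not None:
                values[i, j] = v
    return FeatureMatrix(list(registry), values)
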