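"""End-to-end orchestration: corpus -> candidates -> features -> stacked model.

The :class:`CPIPipeline` bundles the interaction-word dictionary, the
parser adapter, the frozen feature registries and the fitted
:class:`~cpimine.stacker.StackedModel` into one serializable object, so a
trained pipeline reproduces its predictions exactly after a save/load
round trip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np

from cpimine.candidates import (
    CandidateSet,
    InteractionWordEntry,
    build_candidates,
    load_seed_dictionary,
)
from cpimine.depgraph import ParserAdapter, RuleParser, parse
from cpimine.features import (
    DEFAULT_CONFIG,
    FeatureConfig,
    FeatureMatrix,
    candidate_features,
    encode_matrix,
)
from cpimine.io import Corpus, PredictionRecord
from cpimine.stacker import OTHER, StackedModel, StackerConfig

logger = logging.getLogger(__name__)


@dataclass
class CandidateFeatures:
    """Featurized candidates of one corpus, aligned to the candidate set."""

    candset: CandidateSet
    pair_rows: list[dict]
    trip_rows: list[dict]
    pair_labels: np.ndarray
    trip_labels: np.ndarray
    trip_pair_index: list[int]
    trip_positions: list[int]
    trip_words: list[str]


def featurize_corpus(
    corpus: Corpus,
    dictionary: list[InteractionWordEntry],
    adapter: ParserAdapter,
    fcfg: FeatureConfig = DEFAULT_CONFIG,
    *,
    stem: bool = False,
) -> CandidateFeatures:
    """Build candidates and compute full feature dictionaries for both tracks."""
    candset = build_candidates(corpus, dictionary, stem=stem)
    graphs = {}
    pair_rows = []
    for idx in range(len(candset.pairs)):
        masked = candset.masked_for(idx)
        graphs[idx] = parse(masked.tokens, adapter)
        pair_rows.append(candidate_features(masked, graphs[idx], None, fcfg))
    trip_rows, positions, words = [], [], []
    for trip, pidx in zip(candset.triplets, candset.triplet_pair_index):
        masked = candset.masked_for(pidx)
        trip_rows.append(candidate_features(masked, graphs[pidx], trip.match, fcfg))
        positions.append(trip.match.token_index)
        words.append(trip.match.word)
    return CandidateFeatures(
        candset=candset,
        pair_rows=pair_rows,
        trip_rows=trip_rows,
        pair_labels=np.array([p.label for p in candset.pairs], dtype=int),
        trip_labels=np.array([t.label for t in candset.triplets], dtype=int),
        trip_pair_index=list(candset.triplet_pair_index),
        trip_positions=positions,
        trip_words=words,
    )


@dataclass
class CPIPipeline:
    """Train/predict wrapper around the three-stage model."""

    dictionary: list[InteractionWordEntry] = field(default_factory=load_seed_dictionary)
    feature_config: FeatureConfig = DEFAULT_CONFIG
    stacker_config: StackerConfig = field(default_factory=StackerConfig)
    adapter: ParserAdapter | None = None
    stem: bool = False
    pair_registry: list[str] = field(default_factory=list)
    trip_registry: list[str] = field(default_factory=list)
    model: StackedModel | None = None

    def _adapter(self) -> ParserAdapter:
        if self.adapter is None:
            self.adapter = RuleParser(verb_lexicon=[e.word for e in self.dictionary])
        return self.adapter

    def train(self, corpus: Corpus) -> "CPIPipeline":
        """Fit feature registries and the stacked model on a labeled corpus."""
        feats = featurize_corpus(corpus, self.dictionary, self._adapter(),
                                 self.feature_config, stem=self.stem)
        if feats.candset.coverage.get("unreachable"):
            logger.info(
                "%d annotation(s) have no same-sentence candidate (unreachable recall)",
                feats.candset.coverage["unreachable"],
            )
        pair_mat = encode_matrix(feats.pair_rows, fit=True)
        trip_mat = encode_matrix(feats.trip_rows, fit=True)
        self.pair_registry = pair_mat.columns
        self.trip_registry = trip_mat.columns
        self.model = StackedModel.fit(
            pair_mat, feats.pair_labels, trip_mat, feats.trip_labels,
            feats.trip_pair_index, feats.trip_positions, feats.trip_words,
            self.stacker_config,
        )
        return self

    def _encode(self, feats: CandidateFeatures) -> tuple[FeatureMatrix, FeatureMatrix]:
        pair_mat = encode_matrix(feats.pair_rows, registry=self.pair_registry)
        trip_mat = encode_matrix(feats.trip_rows, registry=self.trip_registry)
        return pair_mat, trip_mat

    def predict(self, corpus: Corpus) -> tuple[list[PredictionRecord], CandidateFeatures, dict]:
        """Predict CPR classes for every candidate pair of *corpus*.

        Returns challenge predictions (evaluated groups only, deduplicated
        at the abstract level keeping each pair's best-scoring class), the
        featurized candidates, and the raw per-pair outputs.
        """
        if self.model is None:
            raise RuntimeError("pipeline is not trained")
        feats = featurize_corpus(corpus, self.dictionary, self._adapter(),
                                 self.feature_config, stem=self.stem)
        pair_mat, trip_mat = self._encode(feats)
        out = self.model.predict(pair_mat, trip_mat, feats.trip_pair_index,
                                 feats.trip_positions, feats.trip_words)
        best: dict[tuple[str, int, str, str], float] = {}
        for pair, cls, score in zip(feats.candset.pairs, out["classes"], out["scores"]):
            if cls == OTHER:
                continue
            key = (pair.pmid, int(cls), pair.chem.term_id, pair.prot.term_id)
            if score > best.get(key, -1.0):
                best[key] = float(score)
        preds = [PredictionRecord(p, c, a1, a2) for (p, c, a1, a2) in sorted(best)]
        return preds, feats, out

    def save(self, path: str | Path) -> None:
        joblib.dump(self, Path(path))

    @staticmethod
    def load(path: str | Path) -> "CPIPipeline":
        obj = joblib.load(Path(path))
        if not isinstance(obj, CPIPipeline):
            raise TypeError(f"{path} does not contain a CPIPipeline bundle")
        return obj
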