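"""Building labeled stretch pairs and training the pair-merge classifier.

Labels come from synthetic truth: a consecutive stretch pair is positive
when both stretches lie in the same planted LTR.  Indel-bearing fixtures
are used so that within-LTR score runs genuinely fragment into stretches
with height differences beyond the merger's similarity margin — exactly
the pairs the classifier must learn to rejoin.
"""
from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import detector, merger, repeat_profile, scorer
from .intervals import Interval
from .merger import MergerConfig
from .scorer import ScorerConfig
from .sequence_io import Annotation
from .synthetic_data import PlantSpec, TruthSet, generate_genome, make_semisynthetic


def training_specs(rng: np.random.Generator) -> List[PlantSpec]:
    specs: List[PlantSpec] = []
    for fam in range(3):
        base = dict(
            family_id=f"train{fam}",
            ltr_length=int(rng.integers(300, 900)),
            internal_length=int(rng.integers(800, 2500)),
            ltr_divergence=float(rng.uniform(0.02, 0.1)),
            family_divergence=float(rng.uniform(0.01, 0.06)),
        )
        specs.append(
            PlantSpec(
                **base,
                copy_number=int(rng.integers(3, 6)),
                indel_rate=float(rng.uniform(0.005, 0.02)),
            )
        )
        specs.append(
            PlantSpec(
                family_id=f"train{fam}",
                kind="solo_ltr",
                ltr_length=base["ltr_length"],
                copy_number=1,
                gap_before=(2000, 8000),
            )
        )
        # a nested insertion: mixed-height fragmentation the classifier must
        # learn to rejoin
        specs.append(PlantSpec(**base, nesting=PlantSpec(**base)))
    return specs


def _truth_ltrs(truth: Sequence[Annotation], direction: str) -> List[Interval]:
    """LTR intervals a stretch of the given direction may belong to."""
    ivs: List[Interval] = []
    for a in truth:
        if a.ltr5 is not None:
            ivs.append(a.ltr5)
        if a.ltr3 is not None:
            ivs.append(a.ltr3)
    return ivs


def _assign(stretch_iv: Interval, ltrs: List[Interval]) -> int:
    """Index of the LTR holding most of the stretch, or -1."""
    best, best_ov = -1, 0
    for i, ltr in enumerate(ltrs):
        ov = stretch_iv.overlap_length(ltr)
        if ov > best_ov:
            best, best_ov = i, ov
    if best >= 0 and best_ov * 2 >= len(stretch_iv):
        return best
    return -1


def labeled_pairs_from_truth(
    truth_set: TruthSet,
    scorer_config: ScorerConfig = ScorerConfig(),
    merger_config: MergerConfig = MergerConfig(),
    profile_k: int = repeat_profile.DEFAULT_PROFILE_K,
    semisynthetic_seed: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """(features, labels) for every consecutive same-direction stretch pair."""
    genome = truth_set.genome
    if semisynthetic_seed is not None:
        genome = make_semisynthetic(genome, truth_set.annotations, semisynthetic_seed)
    profile = repeat_profile.train(genome, k=profile_k)
    ltrs = _truth_ltrs(truth_set.annotations, "any")
    feats: List[np.ndarray] = []
    labels: List[int] = []
    for sid, seq in genome.sequences:
        fwd, bwd = scorer.score(seq, scorer_config, sid)
        for track in (fwd, bwd):
            stretches = merger.stretches_from_track(track, merger_config)
            for s1, s2 in zip(stretches, stretches[1:]):
                feats.append(detector.featurize(s1, s2, profile, sid))
                a1 = _assign(s1.interval, ltrs)
                a2 = _assign(s2.interval, ltrs)
                labels.append(1 if a1 >= 0 and a1 == a2 else 0)
    if not feats:
        return np.empty((0, detector.N_FEATURES)), np.empty(0, dtype=np.int64)
    return np.vstack(feats), np.array(labels, dtype=np.int64)


def build_training_set(
    seed: int = 0,
    n_genomes: int = 4,
    background_length: int = 800_000,
) -> Tuple[np.ndarray, np.ndarray]:
    """Generate fixture genomes and collect labeled stretch pairs."""
    rng = np.random.default_rng(seed)
    all_feats: List[np.ndarray] = []
    all_labels: List[np.ndarray] = []
    for g in range(n_genomes):
        specs = training_specs(rng)
        truth_set = generate_genome(
            specs,
            background_length,
            seed=int(rng.integers(0, 2**31)),
            spacing=(10_000, 30_000),
            sequence_id=f"train_g{g}",
        )
        f, l = labeled_pairs_from_truth(
            truth_set, semisynthetic_seed=int(rng.integers(0, 2**31))
        )
        if f.size:
            all_feats.append(f)
            all_labels.append(l)
    return np.vstack(all_feats), np.concatenate(all_labels)


def train_default_model(seed: int = 0, n_search_iterations: int = 40, **kwargs) -> Tuple[detector.MergeModel, Dict[str, float]]:
    features, labels = build_training_set(seed=seed, **kwargs)
    return detector.train_model(
        features, labels, seed=seed, n_search_iterations=n_search_iterations
    )
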