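"""Dataset assembly: negative sampling, upsampling, domain pairing and the
6 x 6 = 36-fold cross-validation plan.

The study design this reproduces: experimentally detected m5U sites are
positives; negatives are undetected uridines drawn from the *same*
transcripts, at 1:10 pos:neg for mRNA-like sets (mimicking the natural
sparsity of the modification) or *all* undetected uridines for tRNA
(about 1:3). mRNA positives and negatives are each split into six
groups; every (positive group, negative group) pairing serves once as
the test set, giving 36 folds. Training positives are upsampled to the
negative count, and the whole target domain is upsampled to the source
size so that every optimizer step sees one batch from each domain.

All sampling is seeded and performed after a canonical sort by
``(transcript_id, position)``, so results do not depend on input row
order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .sequence_io import (SiteRecord, TranscriptSet, extract_window,
                          one_hot_encode)

__all__ = [
    "DomainDataset", "CVPlan", "PairedStream",
    "sample_negatives", "make_cv_plan", "upsample_to_match",
    "pair_domains", "build_domain_dataset",
]


@dataclass
class DomainDataset:
    """Encoded windows + labels for a single domain."""

    encoded: np.ndarray          # (n, L, 4)
    labels: np.ndarray           # (n,) of {0, 1}
    domain: str
    provenance: list[SiteRecord] = field(default_factory=list)

    def __post_init__(self):
        self.encoded = np.asarray(self.encoded, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.encoded) != len(self.labels):
            raise ValueError("encoded and labels length mismatch")
        if self.provenance and len(self.provenance) != len(self.labels):
            raise ValueError("provenance length mismatch")
        if self.domain not in ("source", "target"):
            raise ValueError(f"bad domain {self.domain!r}")

    def __len__(self):
        return len(self.labels)

    def subset(self, idx) -> "DomainDataset":
        idx = np.asarray(idx, dtype=int)
        prov = [self.provenance[i] for i in idx] if self.provenance else []
        return DomainDataset(self.encoded[idx], self.labels[idx],
                             self.domain, prov)

    @property
    def flat_features(self) -> np.ndarray:
        """Windows flattened to (n, L*4) for classical baselines."""
        return self.encoded.reshape(len(self), -1)


def build_domain_dataset(transcripts: TranscriptSet,
                         sites: list[SiteRecord], domain: str,
                         flank: int = 20) -> DomainDataset:
    """Window-extract and one-hot encode a site list into one domain."""
    sites = [s for s in sites if s.domain == domain]
    sites = _canonical_sort(sites)
    mats, labels = [], []
    for s in sites:
        w = extract_window(transcripts, s, flank=flank)
        mats.append(one_hot_encode(w))
        labels.append(s.label)
    return DomainDataset(np.stack(mats) if mats else np.zeros((0, 2 * flank + 1, 4)),
                         np.array(labels, dtype=int), domain, sites)


def _canonical_sort(records: list[SiteRecord]) -> list[SiteRecord]:
    return sorted(records, key=lambda r: (r.transcript_id, r.position, r.label))


def sample_negatives(transcripts: TranscriptSet,
                     positives: list[SiteRecord],
                     ratio: int = 10, seed: int = 0,
                     mode: str = "ratio") -> list[SiteRecord]:
    """Draw negative sites from the transcripts carrying positives.

    Negatives are uridine positions not in the positive set, sampled
    without replacement per transcript. ``mode="ratio"`` draws
    ``min(ratio * n_pos, available)`` per transcript (mRNA/other-RNA
    convention); ``mode="all"`` returns every undetected uridine (tRNA
    convention).
    """
    if mode not in ("ratio", "all"):
        raise ValueError(f"mode must be 'ratio' or 'all', got {mode!r}")
    if mode == "ratio" and ratio < 1:
        raise ValueError("ratio must be >= 1")
    positives = _canonical_sort(positives)
    rng = np.random.default_rng(seed)
    by_transcript: dict[str, list[SiteRecord]] = {}
    for p in positives:
        by_transcript.setdefault(p.transcript_id, []).append(p)
    negatives: list[SiteRecord] = []
    for tid in sorted(by_transcript):
        pos_here = by_transcript[tid]
        pos_positions = {p.position for p in pos_here}
        seq = transcripts[tid]
        candidates = [i for i, b in enumerate(seq)
                      if b == "U" and i not in pos_positions]
        if not candidates:
            warnings.warn(
                f"transcript {tid!r} has positives but no spare uridine; "
                "zero negatives sampled", stacklevel=2)
            continue
        domain = pos_here[0].domain
        if mode == "all":
            chosen = candidates
        else:
            k = min(ratio * len(pos_here), len(candidates))
            chosen = sorted(rng.choice(candidates, size=k, replace=False))
        negatives.extend(
            SiteRecord(tid, int(i), 0, domain, pos_here[0].tags)
            for i in chosen)
    return negatives


@dataclass
class CVPlan:
    """All (positive group, negative group) test pairings.

    ``pos_groups`` / ``neg_groups`` map record keys to a group index in
    ``range(groups)``; ``folds`` enumerates every (i, j) pairing, so a
    6-group plan has 36 folds.
    """

    groups: int
    pos_groups: dict[tuple, int]
    neg_groups: dict[tuple, int]

    @property
    def folds(self) -> list[tuple[int, int]]:
        return [(i, j) for i in range(self.groups)
                for j in range(self.groups)]

    def test_keys(self, fold: tuple[int, int]) -> set:
        i, j = fold
        return ({k for k, g in self.pos_groups.items() if g == i}
                | {k for k, g in self.neg_groups.items() if g == j})

    def train_keys(self, fold: tuple[int, int]) -> set:
        i, j = fold
        return ({k for k, g in self.pos_groups.items() if g != i}
                | {k for k, g in self.neg_groups.items() if g != j})

    def to_json(self, path):
        doc = {
            "groups": self.groups,
            "pos_groups": {f"{t}:{p}": g
                           for (t, p), g in self.pos_groups.items()},
            "neg_groups": {f"{t}:{p}": g
                           for (t, p), g in self.neg_groups.items()},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CVPlan":
        with open(path) as fh:
            doc = json.load(fh)

        def parse(d):
            out = {}
            for key, g in d.items():
                tid, pos = key.rsplit(":", 1)
                out[(tid, int(pos))] = g
            return out

        return cls(doc["groups"], parse(doc["pos_groups"]),
                   parse(doc["neg_groups"]))


def make_cv_plan(pos_ids: list[tuple], neg_ids: list[tuple],
                 groups: int = 6, seed: int = 0) -> CVPlan:
    """Randomly partition positives and negatives into near-equal groups.

    Ids are ``(transcript_id, position)`` keys. Every pairing of one
    positive group with one negative group is a fold: ``groups ** 2``
    folds in total (36 for the default six groups).
    """
    if len(pos_ids) < groups or len(neg_ids) < groups:
        raise ValueError(
            f"need at least {groups} ids per label for {groups} groups")
    if len(set(pos_ids)) != len(pos_ids) or len(set(neg_ids)) != len(neg_ids):
        raise ValueError("duplicate ids in input")
    rng = np.random.default_rng(seed)

    def assign(ids):
        ids = sorted(ids)
        perm = rng.permutation(len(ids))
        return {ids[p]: int(k % groups) for k, p in enumerate(perm)}

    return CVPlan(groups, assign(pos_ids), assign(neg_ids))


def upsample_to_match(records, target_count: int, seed: int = 0):
    """Upsample with replacement to ``target_count``, keeping every
    original at least once (stratified replication then a seeded top-up).
    """
    records = list(records)
    if not records:
        raise ValueError("cannot upsample an empty record list")
    if target_count < len(records):
        raise ValueError(
            f"target_count {target_count} < len(records) {len(records)}")
    reps = target_count // len(records)
    out = records * reps
    remainder = target_count - len(out)
    if remainder:
        rng = np.random.default_rng(seed)
        extra = rng.choice(len(records), size=remainder, replace=False)
        out.extend(records[i] for i in sorted(extra))
    return out


def _upsample_dataset(ds: DomainDataset, target_count: int,
                      seed: int) -> DomainDataset:
    idx = upsample_to_match(list(range(len(ds))), target_count, seed)
    return ds.subset(np.array(idx))


@dataclass
class PairedStream:
    """Seeded stream of paired (source, target) mini-batches.

    The target domain is first upsampled to the source size; both are
    then shuffled with the seed and chopped into equal-size sub-batches,
    so one epoch touches each source record exactly once.
    """

    source: DomainDataset
    target: DomainDataset
    batch_size: int
    seed: int

    def __post_init__(self):
        if len(self.source) == 0 or len(self.target) == 0:
            raise ValueError("both domains must be non-empty")
        self.target = _upsample_dataset(self.target, len(self.source),
                                        self.seed)

    @property
    def steps_per_epoch(self) -> int:
        return int(np.ceil(len(self.source) / self.batch_size))

    def epoch(self, epoch_index: int = 0):
        """Yield (source_batch, target_batch) DomainDataset pairs."""
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, epoch_index]))
        n = len(self.source)
        sperm = rng.permutation(n)
        tperm = rng.permutation(n)
        for lo in range(0, n, self.batch_size):
            sl = sperm[lo:lo + self.batch_size]
            tl = tperm[lo:lo + self.batch_size]
            yield self.source.subset(sl), self.target.subset(tl)


def pair_domains(source: DomainDataset, target: DomainDataset,
                 batch: int = 64, seed: int = 0) -> PairedStream:
    """Build the paired training stream (see :class:`PairedStream`)."""
    return PairedStream(source, target, batch, seed)
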