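"""Synthetic paired-domain benchmark generator.

Emulates the two-domain structure of the m5U transfer-learning problem
without any download: two sets of 41-nt uridine-centred windows whose
positives share one planted motif (the transferable signal), while each
domain's positives additionally carry a *private* label-correlated
confounder motif and the two domains differ in background G+C content.
A source-only classifier is thereby tempted by the confounder and the
composition shift; a model that isolates the shared signal transfers
better — exactly the property the domain-separation network is meant
to have.

Every motif insertion is recorded in a planting log so attribution-based
motif recovery can be scored against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datasets import DomainDataset
from .sequence_io import (SiteRecord, TranscriptSet,
                          write_fasta, write_site_table)

__all__ = ["SynthConfig", "generate_domain_pair", "write_fixture",
           "read_fixture", "PRESETS", "preset_config"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    Defaults define the standard "confounded" study condition:
    ~2000 windows per domain, source balanced (the tRNA-like domain is
    label-rich), target at the natural-sparsity 1:10 pos:neg ratio,
    shared motif in 90% of positives, private confounders in 60%, and a
    background G+C shift between the domains.
    """

    length: int = 41
    n_source_pos: int = 1000
    n_source_neg: int = 1000
    n_target_pos: int = 180
    n_target_neg: int = 1800
    shared_motif: str = "GUUCGA"
    source_private_motif: str = "AGGAGG"
    target_private_motif: str = "CCAUCC"
    motif_prob: float = 0.9
    confounder_prob: float = 0.6
    shared_anchor: int = 6
    private_anchor: int = 28
    jitter: int = 3
    source_gc: float = 0.55
    target_gc: float = 0.40
    seed: int = 0

    def __post_init__(self):
        if self.length % 2 == 0:
            raise ValueError("window length must be odd")
        for p in (self.motif_prob, self.confounder_prob,
                  self.source_gc, self.target_gc):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        center = self.length // 2
        for name, motif, anchor in (
                ("shared", self.shared_motif, self.shared_anchor),
                ("private", max(self.source_private_motif,
                                self.target_private_motif, key=len),
                 self.private_anchor)):
            if len(motif) >= self.length:
                raise ValueError(f"{name} motif longer than window")
            lo = anchor - self.jitter
            hi = anchor + self.jitter + len(motif)
            if lo < 0 or hi > self.length:
                raise ValueError(
                    f"{name} motif anchor range [{lo}, {hi}) outside window")
            if lo <= center < hi:
                raise ValueError(
                    f"{name} motif anchor range overlaps the centre uridine")
        shared_hi = self.shared_anchor + self.jitter + len(self.shared_motif)
        private_lo = self.private_anchor - self.jitter
        if shared_hi > private_lo:
            raise ValueError("shared and private anchor ranges overlap")


# All presets share one data scale (~2000 windows per domain, target at
# the natural-sparsity 1:10 ratio) and differ only in signal structure.
PRESETS = {
    # clean shared signal in every positive, no confounders, matched
    # background composition
    "easy": dict(motif_prob=1.0, confounder_prob=0.0,
                 source_gc=0.5, target_gc=0.5),
    # shared signal + background composition shift only
    "shifted": dict(motif_prob=0.9, confounder_prob=0.0),
    # full study condition (the SynthConfig defaults)
    "confounded": dict(),
}


def preset_config(name: str, seed: int = 0, **overrides) -> SynthConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; options: {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return SynthConfig(seed=seed, **kwargs)


def _draw_background(rng: np.random.Generator, n: int, length: int,
                     gc: float) -> np.ndarray:
    """i.i.d. background: P(G)=P(C)=gc/2, P(A)=P(U)=(1-gc)/2."""
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G U
    return rng.choice(4, size=(n, length), p=probs)


_BASE_INDEX = {b: i for i, b in enumerate("ACGU")}


def _plant(rows: np.ndarray, which: np.ndarray, motif: str, anchor: int,
           jitter: int, rng: np.random.Generator, log: list, domain: str,
           kind: str, index_offset: int):
    codes = np.array([_BASE_INDEX[b] for b in motif])
    for i in np.flatnonzero(which):
        off = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
        start = anchor + off
        rows[i, start:start + len(codes)] = codes
        log.append({"domain": domain, "index": int(i + index_offset),
                    "motif": motif, "kind": kind, "start": start})


def _make_domain(cfg: SynthConfig, domain: str, rng: np.random.Generator,
                 log: list) -> DomainDataset:
    if domain == "source":
        n_pos, n_neg, gc = cfg.n_source_pos, cfg.n_source_neg, cfg.source_gc
        private = cfg.source_private_motif
    else:
        n_pos, n_neg, gc = cfg.n_target_pos, cfg.n_target_neg, cfg.target_gc
        private = cfg.target_private_motif
    n = n_pos + n_neg
    rows = _draw_background(rng, n, cfg.length, gc)
    rows[:, cfg.length // 2] = _BASE_INDEX["U"]  # centre always U
    labels = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
    if n_pos:
        has_shared = rng.random(n_pos) < cfg.motif_prob
        _plant(rows[:n_pos], has_shared, cfg.shared_motif, cfg.shared_anchor,
               cfg.jitter, rng, log, domain, "shared", 0)
        if private:
            has_conf = rng.random(n_pos) < cfg.confounder_prob
            _plant(rows[:n_pos], has_conf, private, cfg.private_anchor,
                   cfg.jitter, rng, log, domain, "private", 0)
    encoded = np.eye(4)[rows]
    sites = [SiteRecord(f"{domain}_{i:05d}", cfg.length // 2,
                        int(labels[i]), domain)
             for i in range(n)]
    return DomainDataset(encoded, labels, domain, sites)


def generate_domain_pair(config: SynthConfig):
    """Generate (source, target, planting_log) from a config.

    The planting log is a list of dicts, one per motif insertion:
    domain, window index within that domain, motif string, kind
    (shared/private), and 0-based start offset.
    """
    rng = np.random.default_rng(config.seed)
    log: list[dict] = []
    source = _make_domain(config, "source", rng, log)
    target = _make_domain(config, "target", rng, log)
    return source, target, log


def write_fixture(source: DomainDataset, target: DomainDataset, log: list,
                  out_dir, overwrite: bool = False):
    """Write a fixture directory: window FASTA + site TSV per domain and
    the planting log JSON; round-trippable through :mod:`seqdsn.sequence_io`.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty; "
                              "pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)
    from .sequence_io import decode_one_hot
    for ds in (source, target):
        if len(ds) == 0:
            continue
        ts = TranscriptSet()
        for rec, mat in zip(ds.provenance, ds.encoded):
            ts.add(rec.transcript_id, decode_one_hot(mat))
        write_fasta(ts, out / f"{ds.domain}.fasta")
        write_site_table(ds.provenance, out / f"{ds.domain}_sites.tsv")
    with open(out / "planting_log.json", "w") as fh:
        json.dump(log, fh, indent=1)
    return out


def read_fixture(fixture_dir):
    """Load a fixture directory back into (source, target, log)."""
    from .sequence_io import read_fasta, read_site_table
    from .datasets import build_domain_dataset
    out = []
    fixture_dir = Path(fixture_dir)
    for domain in ("source", "target"):
        fasta = fixture_dir / f"{domain}.fasta"
        if not fasta.exists():
            out.append(None)
            continue
        ts = read_fasta(fasta)
        sites = read_site_table(fixture_dir / f"{domain}_sites.tsv")
        flank = len(next(iter(ts.entries.values()))) // 2
        out.append(build_domain_dataset(ts, sites, domain, flank=flank))
    with open(fixture_dir / "planting_log.json") as fh:
        log = json.load(fh)
    return out[0], out[1], log
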