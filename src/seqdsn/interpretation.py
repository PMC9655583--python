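"""Integrated Gradients attribution and simplified motif aggregation.

Attribution follows the path-integral definition: for input x and
baseline b,

    IG_i(x) = (x_i - b_i) * mean_{k=1..m} dF/dx_i |_{b + (k/m)(x - b)}

where F is the positive-class score of the designated classifier head
(target head in dual mode, source head otherwise). The default baseline
is the all-zero matrix — the same convention as an all-N window. The
completeness gap |sum IG - (F(x) - F(b))| is reported with every map and
shrinks as the number of integration steps grows.

Motif aggregation is a deliberately simple seqlet -> cluster -> align
procedure standing in for the full TF-MoDISco pipeline: high-weight
k-windows are extracted per attribution map, linked by best-offset
cross-correlation, aligned within clusters and summarized as position
frequency matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor
from .sequence_io import CHANNELS, decode_one_hot

__all__ = ["AttributionMap", "Seqlet", "Motif", "integrated_gradients",
           "extract_seqlets", "cluster_and_align", "write_meme",
           "consensus_string", "hamming_best_overlap"]


@dataclass
class AttributionMap:
    matrix: np.ndarray           # (L, 4) signed attributions
    window: np.ndarray           # (L, 4) input one-hot
    prediction: float
    baseline_value: float
    convergence_gap: float

    @property
    def sequence(self) -> str:
        return decode_one_hot(self.window.astype(int))

    @property
    def per_base_weight(self) -> np.ndarray:
        """Attribution at the realized base per position (length L)."""
        return (self.matrix * self.window).sum(axis=1)

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("position\tA\tC\tG\tU\tbase\tweight\n")
            seq = self.sequence
            w = self.per_base_weight
            for i, row in enumerate(self.matrix):
                vals = "\t".join(f"{v:.6g}" for v in row)
                fh.write(f"{i}\t{vals}\t{seq[i]}\t{w[i]:.6g}\n")


@dataclass(frozen=True)
class Seqlet:
    map_index: int
    start: int
    seq: str
    weight: float

    @property
    def one_hot(self) -> np.ndarray:
        from .sequence_io import one_hot_encode
        return one_hot_encode(self.seq)


@dataclass
class Motif:
    pfm: np.ndarray              # (width, 4), rows sum to 1
    support: int
    mean_weight: float
    members: list[Seqlet] = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.pfm.shape[0]

    @property
    def consensus(self) -> str:
        return consensus_string(self.pfm)


def consensus_string(pfm: np.ndarray) -> str:
    return "".join(CHANNELS[i] for i in np.argmax(pfm, axis=1))


def integrated_gradients(score_fn, x: np.ndarray,
                         baseline: np.ndarray | None = None,
                         steps: int = 50) -> AttributionMap:
    """Integrated Gradients for one encoded window.

    ``score_fn`` maps a batched input Tensor (n, L, 4) to a score Tensor
    (n,); use :meth:`DSNModel.score_fn` for a trained network (put the
    model in eval mode first). The path integral is approximated by the
    midpoint rule (interpolation points (k - 1/2)/steps), whose error
    decays quadratically in the step count; all points are evaluated in
    a single batched forward/backward pass.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    x = np.asarray(x, dtype=float)
    baseline = (np.zeros_like(x) if baseline is None
                else np.asarray(baseline, dtype=float))
    if baseline.shape != x.shape:
        raise ValueError("baseline shape must match input shape")
    alphas = (np.arange(1, steps + 1) - 0.5) / steps
    points = baseline[None] + alphas[:, None, None] * (x - baseline)[None]
    pts = Tensor(points, requires_grad=True)
    scores = score_fn(pts)
    scores.sum().backward()
    avg_grad = pts.grad.mean(axis=0)
    attr = (x - baseline) * avg_grad
    from .autograd import no_grad
    with no_grad():
        f_x = float(score_fn(Tensor(x[None])).data[0])
        f_b = float(score_fn(Tensor(baseline[None])).data[0])
    gap = abs(attr.sum() - (f_x - f_b))
    return AttributionMap(attr, x, f_x, f_b, gap)


def extract_seqlets(maps: list[AttributionMap], k: int = 6,
                    min_score: float = 0.5) -> list[Seqlet]:
    """High-weight k-windows from positively predicted attribution maps.

    Per map, the weight of each sliding k-window is the sum of per-base
    attributions; windows strictly above the map's mean k-window weight
    are candidate seqlets, and overlapping candidates are merged keeping
    the highest-weight one.
    """
    seqlets: list[Seqlet] = []
    for mi, amap in enumerate(maps):
        L = amap.matrix.shape[0]
        if k > L:
            raise ValueError(f"seqlet length {k} exceeds window length {L}")
        if amap.prediction < min_score:
            continue
        w = amap.per_base_weight
        sums = np.convolve(w, np.ones(k), mode="valid")
        mean = sums.mean()
        candidates = [(float(sums[s]), s) for s in range(len(sums))
                      if sums[s] > mean]
        candidates.sort(reverse=True)
        taken: list[int] = []
        seq = amap.sequence
        for weight, start in candidates:
            if any(abs(start - t) < k for t in taken):
                continue
            taken.append(start)
            seqlets.append(Seqlet(mi, start, seq[start:start + k], weight))
    return seqlets


def _best_offset(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Max cross-correlation of two one-hot seqlets over all offsets.

    Returns (score, offset of b relative to a); the score counts
    matching positions at the best alignment.
    """
    k = a.shape[0]
    best, best_off = -1.0, 0
    for off in range(-(k - 1), k):
        if off >= 0:
            ov = (a[off:] * b[:k - off]).sum()
        else:
            ov = (a[:k + off] * b[-off:]).sum()
        if ov > best:
            best, best_off = float(ov), off
    return best, best_off


def cluster_and_align(seqlets: list[Seqlet], min_support: int = 5,
                      link_threshold: float | None = None,
                      pseudocount: float = 0.25) -> list[Motif]:
    """Greedy agglomeration of seqlets into aligned motifs.

    Pairs whose best-offset cross-correlation exceeds the link threshold
    (default 0.7 * k) fall in one cluster (single linkage via connected
    components); each cluster is aligned at best offsets against its
    highest-weight member and summarized as a pseudocount-smoothed PFM.
    Clusters below ``min_support`` are dropped; motifs are sorted by
    mean seqlet weight, descending.
    """
    if not seqlets:
        warnings.warn("no seqlets to cluster", stacklevel=2)
        return []
    k = len(seqlets[0].seq)
    if any(len(s.seq) != k for s in seqlets):
        raise ValueError("all seqlets must share one length")
    thr = link_threshold if link_threshold is not None else 0.7 * k
    n = len(seqlets)
    mats = [s.one_hot for s in seqlets]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            score, _ = _best_offset(mats[i], mats[j])
            if score > thr:
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pj] = pi

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    motifs = []
    for members in clusters.values():
        if len(members) < min_support:
            continue
        ref = max(members, key=lambda i: seqlets[i].weight)
        offsets = {}
        for i in members:
            _, off = _best_offset(mats[ref], mats[i])
            offsets[i] = off
        lo = min(offsets.values())
        hi = max(off + k for off in offsets.values())
        width = hi - lo
        counts = np.full((width, 4), pseudocount)
        for i in members:
            start = offsets[i] - lo
            counts[start:start + k] += mats[i]
        pfm = counts / counts.sum(axis=1, keepdims=True)
        weights = [seqlets[i].weight for i in members]
        motifs.append(Motif(pfm, len(members), float(np.mean(weights)),
                            [seqlets[i] for i in members]))
    if not motifs:
        warnings.warn(f"no cluster reached min_support={min_support}",
                      stacklevel=2)
    motifs.sort(key=lambda m: -m.mean_weight)
    return motifs


def hamming_best_overlap(consensus: str, motif: str) -> int:
    """Minimum mismatches of ``motif`` against any full-length placement
    inside (or equal to) ``consensus``; used to score motif recovery."""
    if len(motif) > len(consensus):
        consensus, motif = motif, consensus
    best = len(motif)
    for off in range(len(consensus) - len(motif) + 1):
        mism = sum(a != b for a, b in
                   zip(consensus[off:off + len(motif)], motif))
        best = min(best, mism)
    return best


def write_meme(motifs: list[Motif], path, alphabet: str = "ACGU"):
    """Export motifs in MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= " + alphabet + "\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} 0.25" for b in alphabet) + "\n\n")
        for mi, m in enumerate(motifs):
            fh.write(f"MOTIF motif_{mi + 1} {m.consensus}\n")
            fh.write(f"letter-probability matrix: alength= 4 "
                     f"w= {m.width} nsites= {m.support}\n")
            for row in m.pfm:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def render_logo(motif: Motif, path):
    """Render a sequence logo if ``logomaker`` is importable (optional)."""
    try:
        import logomaker
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import pandas as pd
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("logo rendering requires logomaker") from exc
    df = pd.DataFrame(motif.pfm, columns=list(CHANNELS))
    logomaker.Logo(df)
    plt.savefig(path)
    plt.close()
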