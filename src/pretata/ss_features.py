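"""473-dimension global + local features from a predicted secondary structure.

The input is the three-state string (H = helix, E = strand, C = coil) that a
secondary-structure predictor such as PSIPRED assigns to a protein. The
default scheme combines standard descriptor families into exactly 473 values:

====  =========================================================  ====
block  content                                                   dims
====  =========================================================  ====
kmer   word frequencies over {H,E,C} for k = 1..5 (percent of
       windows), 3 + 9 + 27 + 81 + 243                            363
ctd    C/T/D treating the three states as the three groups         21
posbin per-bin state composition over 8 equal position bins        24
seg    per state: segment count /L, mean and max segment
       length /L (all x100)                                         9
hist   per state: segment-length histogram, lengths 1..17 and
       >=18, percent of that state's segments                      54
runs   longest H run /L x100, longest E run /L x100                 2
====  =========================================================  ====

Every feature is on a 0-100 scale. The scheme is configurable; the default
preset is the one the rest of the pipeline (661D joint vector) assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .ctd import DomainError, PropertyGrouping, ctd_for_property, ctd_feature_names
from .seqio import SS_ALPHABET, SSRecord, FeatureTable

SS_STATES = "HEC"

# The three states act as their own CTD "groups".
SS_GROUPING = PropertyGrouping.from_strings(
    "ssctd", "H", "E", "C", alphabet=SS_STATES
)


@dataclass(frozen=True)
class SSFeatureScheme:
    """Parameters of the secondary-structure feature blocks."""

    kmer_sizes: tuple[int, ...] = (1, 2, 3, 4, 5)
    n_position_bins: int = 8
    hist_max_length: int = 18  # lengths 1..17 binned singly, >=18 pooled
    lenient: bool = False      # zero-fill k-mer blocks too wide for the input

    @property
    def block_dims(self) -> list[tuple[str, int]]:
        dims = [(f"kmer{k}", 3 ** k) for k in self.kmer_sizes]
        dims.append(("ctd", 21))
        dims.append(("posbin", 3 * self.n_position_bins))
        dims.append(("seg", 9))
        dims.append(("hist", 3 * self.hist_max_length))
        dims.append(("runs", 2))
        return dims

    @property
    def total_dim(self) -> int:
        return sum(d for _, d in self.block_dims)


DEFAULT_SCHEME = SSFeatureScheme()
assert DEFAULT_SCHEME.total_dim == 473


def ss_segments(ss: str) -> list[tuple[str, int, int]]:
    """Maximal same-state runs as (state, 1-based start, length) triples."""
    if not ss:
        raise DomainError("empty secondary-structure string")
    segs = []
    start = 0
    for i in range(1, len(ss) + 1):
        if i == len(ss) or ss[i] != ss[start]:
            segs.append((ss[start], start + 1, i - start))
            start = i
    return segs


def _kmer_block(ss: str, k: int, lenient: bool) -> np.ndarray:
    n_windows = len(ss) - k + 1
    words = ["".join(w) for w in product(SS_STATES, repeat=k)]
    if n_windows < 1:
        if lenient:
            return np.zeros(len(words))
        raise DomainError(
            f"structure string of length {len(ss)} is shorter than k-mer "
            f"size {k}; pad the input or use a reduced scheme"
        )
    index = {w: i for i, w in enumerate(words)}
    counts = np.zeros(len(words))
    for i in range(n_windows):
        counts[index[ss[i: i + k]]] += 1
    return counts / n_windows * 100.0


def _position_bins(ss: str, n_bins: int) -> np.ndarray:
    # residue r (1-based) falls in bin ceil(n_bins * r / L)
    L = len(ss)
    out = np.zeros((n_bins, 3))
    counts = np.zeros(n_bins)
    for r, c in enumerate(ss, start=1):
        b = -(-n_bins * r // L) - 1
        out[b, SS_STATES.index(c)] += 1
        counts[b] += 1
    nonzero = counts > 0
    out[nonzero] = out[nonzero] / counts[nonzero, None] * 100.0
    return out.ravel()


def _segment_stats(ss: str, hist_max_length: int) -> tuple[np.ndarray, np.ndarray]:
    L = len(ss)
    segs = ss_segments(ss)
    stats = np.zeros((3, 3))
    hists: dict[str, list[int]] = {s: [] for s in SS_STATES}
    for state, _start, length in segs:
        hists[state].append(length)
    for si, state in enumerate(SS_STATES):
        lens = hists[state]
        if lens:
            stats[si] = (
                len(lens) / L * 100.0,
                float(np.mean(lens)) / L * 100.0,
                max(lens) / L * 100.0,
            )
    return stats.ravel(), _length_histograms(hists, hist_max_length)


def _length_histograms(hists: dict[str, list[int]], max_len: int) -> np.ndarray:
    out = np.zeros((3, max_len))
    for si, state in enumerate(SS_STATES):
        lens = hists[state]
        if not lens:
            continue
        for length in lens:
            out[si, min(length, max_len) - 1] += 1
        out[si] = out[si] / len(lens) * 100.0
    return out.ravel()


def extract_ss473(ss: str, scheme: SSFeatureScheme = DEFAULT_SCHEME) -> np.ndarray:
    """The full secondary-structure feature vector (473 under the default)."""
    if not ss or set(ss) - set(SS_ALPHABET):
        raise DomainError(f"invalid secondary-structure string {ss!r}")
    max_k = max(scheme.kmer_sizes)
    if len(ss) < max_k and not scheme.lenient:
        raise DomainError(
            f"structure string of length {len(ss)} is shorter than the "
            f"largest k-mer ({max_k}); pad the input or use a reduced scheme"
        )
    parts = [_kmer_block(ss, k, scheme.lenient) for k in scheme.kmer_sizes]
    parts.append(ctd_for_property(ss, SS_GROUPING))
    parts.append(_position_bins(ss, scheme.n_position_bins))
    stats, hist = _segment_stats(ss, scheme.hist_max_length)
    parts.append(stats)
    parts.append(hist)
    L = len(ss)
    longest = {s: 0 for s in SS_STATES}
    for state, _start, length in ss_segments(ss):
        longest[state] = max(longest[state], length)
    parts.append(np.array([longest["H"] / L * 100.0, longest["E"] / L * 100.0]))
    vec = np.concatenate(parts)
    assert vec.size == scheme.total_dim
    return vec


def feature_names_ss473(scheme: SSFeatureScheme = DEFAULT_SCHEME) -> list[str]:
    names: list[str] = []
    for k in scheme.kmer_sizes:
        names += [f"ss.kmer{k}.{''.join(w)}" for w in product(SS_STATES, repeat=k)]
    names += [f"ss.{n}" for n in ctd_feature_names(SS_GROUPING)]
    for b in range(scheme.n_position_bins):
        names += [f"ss.posbin{b + 1}.{s}" for s in SS_STATES]
    for s in SS_STATES:
        names += [f"ss.seg.{s}.count", f"ss.seg.{s}.meanlen", f"ss.seg.{s}.maxlen"]
    for s in SS_STATES:
        names += [f"ss.hist.{s}.len{l}" for l in range(1, scheme.hist_max_length)]
        names += [f"ss.hist.{s}.len{scheme.hist_max_length}plus"]
    names += ["ss.longest_run.H", "ss.longest_run.E"]
    return names


def extract_ss473_table(
    records: list[SSRecord],
    scheme: SSFeatureScheme = DEFAULT_SCHEME,
    labels: list[str] | None = None,
) -> FeatureTable:
    values = (
        np.vstack([extract_ss473(r.ss, scheme) for r in records])
        if records else np.empty((0, scheme.total_dim))
    )
    return FeatureTable(
        row_ids=[r.id for r in records],
        feature_names=feature_names_ss473(scheme),
        values=values,
        labels=labels,
    )


def extract_661_table(
    proteins, ss_records, labels: list[str] | None = None,
    groupings=None, scheme: SSFeatureScheme = DEFAULT_SCHEME,
) -> FeatureTable:
    """Joint 661D vector: 188D primary-sequence block then 473D SS block.

    Records are paired by id; unpaired ids on either side are an error.
    """
    from .ctd import DEFAULT_GROUPINGS, extract_188_table

    groupings = groupings or DEFAULT_GROUPINGS
    ss_by_id = {r.id: r for r in ss_records}
    prot_ids = {r.id for r in proteins}
    missing_ss = [r.id for r in proteins if r.id not in ss_by_id]
    missing_prot = sorted(set(ss_by_id) - prot_ids)
    if missing_ss or missing_prot:
        raise DomainError(
            f"unpaired records: no secondary structure for {missing_ss!r}; "
            f"no protein sequence for {missing_prot!r}"
        )
    t188 = extract_188_table(proteins, groupings)
    t473 = extract_ss473_table([ss_by_id[r.id] for r in proteins], scheme)
    return FeatureTable(
        row_ids=t188.row_ids,
        feature_names=t188.feature_names + t473.feature_names,
        values=np.hstack([t188.values, t473.values]),
        labels=labels,
    )
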