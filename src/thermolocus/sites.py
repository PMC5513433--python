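"""Binding-site calling and per-position statistical weights.

Both strands are scanned with each log-odds PWM; a site is called wherever
the score strictly exceeds the threshold (default 0, the value used at locus
scale).  Reverse-strand hits are found by scanning the reverse complement
and are reported in forward-strand coordinates.  Positions containing N are
never called (they score -inf).

A called site i of TF a carries the statistical weight

    q_i(x) = A_a * [a](x) * exp((s_i - s_max,a) / lambda_a)

at axis position x, where [a](x) is the TF concentration profile.  Larger
``lambda`` compresses affinity differences between strong and weak sites,
guarding against over-specified PWMs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AccessibilityMask, LocusSequence, ProfileTable, PWMRecord, BASE_ORDER
from .params import ParameterSet

_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0, 4: 4}  # A<->T, C<->G, N<->N
_ENCODE = {b: i for i, b in enumerate(BASE_ORDER + "N")}


@dataclass(frozen=True)
class BindingSite:
    """A located, stranded, scored PWM match (locus-local, 0-based half-open)."""

    site_id: int
    tf_name: str
    start: int
    end: int
    strand: str  # "+" | "-"
    score: float

    @property
    def footprint(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class SiteWeightMatrix:
    """q[i, x]: statistical weight of site i at axis position x (>= 0)."""

    sites: tuple[BindingSite, ...]
    q: np.ndarray  # shape (n_sites, n_positions)


_ENCODE_TABLE = np.full(256, 4, dtype=np.int8)
for _b, _i in _ENCODE.items():
    _ENCODE_TABLE[ord(_b)] = _i


def encode(bases: str) -> np.ndarray:
    return _ENCODE_TABLE[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]


def _scan_scores(pwm: PWMRecord, codes: np.ndarray) -> np.ndarray:
    """Score every start offset of one strand; windows touching N score -inf."""
    L = pwm.length
    n = codes.size - L + 1
    # 5th column handles N: -inf so any window containing N is never called
    lookup = np.hstack([pwm.matrix, np.full((L, 1), -np.inf)])
    scores = np.zeros(n)
    for off in range(L):
        scores += lookup[off, codes[off:off + n]]
    return scores


def scan(pwm: PWMRecord, seq: LocusSequence, threshold: float = 0.0,
         id_offset: int = 0) -> list[BindingSite]:
    """Call sites with score > threshold on both strands, sorted by start.

    Opposite-strand hits at the same start are both reported ("+" first);
    steric exclusion between them is the occupancy module's concern.
    """
    L = pwm.length
    if L > seq.length:
        raise ValueError(f"PWM {pwm.tf_name} (length {L}) longer than sequence ({seq.length})")
    codes = encode(seq.bases)
    fwd = _scan_scores(pwm, codes)
    comp = np.array([3, 2, 1, 0, 4], dtype=np.int8)
    rc = comp[codes[::-1]]
    rev = _scan_scores(pwm, rc)[::-1]  # rev[i] scores the window starting at i, minus strand

    hits: list[tuple[int, str, float]] = []
    for i in np.nonzero(fwd > threshold)[0]:
        hits.append((int(i), "+", float(fwd[i])))
    for i in np.nonzero(rev > threshold)[0]:
        hits.append((int(i), "-", float(rev[i])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return [
        BindingSite(id_offset + k, pwm.tf_name, start, start + L, strand, score)
        for k, (start, strand, score) in enumerate(hits)
    ]


def scan_all(pwms, seq: LocusSequence, threshold: float = 0.0) -> list[BindingSite]:
    """Scan every PWM, pooling sites sorted by (start, end, tf, strand)."""
    pooled: list[BindingSite] = []
    for pwm in pwms:
        pooled.extend(scan(pwm, seq, threshold))
    pooled.sort(key=lambda s: (s.start, s.end, s.tf_name, s.strand))
    return [
        BindingSite(k, s.tf_name, s.start, s.end, s.strand, s.score)
        for k, s in enumerate(pooled)
    ]


def apply_mask(sites, mask: AccessibilityMask | None, enabled: bool = True) -> list[BindingSite]:
    """Keep sites whose full footprint lies within accessible chromatin.

    With ``enabled`` false (or no mask given) this is the identity.  The
    containment rule reads "within accessible chromatin" strictly: a footprint
    straddling an accessibility boundary is dropped.  ``any_overlap=True`` on
    :func:`apply_mask_overlap` gives the permissive variant.
    """
    if not enabled or mask is None:
        return list(sites)
    return [s for s in sites if mask.contains(s.start, s.end)]


def apply_mask_overlap(sites, mask: AccessibilityMask) -> list[BindingSite]:
    """Permissive masking variant: keep sites overlapping any accessible bp."""
    return [s for s in sites if mask.overlaps(s.start, s.end)]


def site_weights(sites, params: ParameterSet, profiles: ProfileTable,
                 pwms) -> SiteWeightMatrix:
    """q[i, x] = A_a * [a](x) * exp((s_i - s_max,a) / lambda_a)."""
    smax = {p.tf_name: p.s_max for p in pwms}
    n, P = len(sites), profiles.n_positions
    q = np.empty((n, P))
    for i, site in enumerate(sites):
        if site.tf_name not in params.tfs:
            raise KeyError(f"no parameters for TF {site.tf_name!r}")
        if site.tf_name not in profiles:
            raise KeyError(f"no concentration column for TF {site.tf_name!r}")
        tf = params.tfs[site.tf_name]
        affinity = np.exp((site.score - smax[site.tf_name]) / tf.lam)
        q[i] = tf.A * profiles[site.tf_name] * affinity
    return SiteWeightMatrix(tuple(sites), q)


def sites_to_bed6(sites, path, chrom: str = "locus") -> None:
    """Export called sites as BED6 (name = TF, score rescaled to 0-1000)."""
    scores = np.array([s.score for s in sites], dtype=float)
    if scores.size:
        lo, hi = scores.min(), scores.max()
        span = hi - lo if hi > lo else 1.0
    with open(path, "w") as fh:
        for s in sites:
            bed_score = int(round(1000 * (s.score - lo) / span)) if scores.size else 0
            fh.write(f"{chrom}\t{s.start}\t{s.end}\t{s.tf_name}\t{bed_score}\t{s.strand}\n")
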