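"""Average nucleotide identity (ANIb) from pairwise alignment coordinate tables.

Fragments on the reference frame are first de-duplicated (a fragment wholly
contained in another is removed), then fragments overlapping by more than 10%
of the shorter fragment's length are joined into one spanning fragment whose
identity is the length-weighted mean of the two (overlap counted once); the
rules are applied left-to-right by start coordinate until a fixpoint. ANIb is
the size-weighted mean identity of the merged fragments.

Coordinates are 1-based inclusive, as printed by show-coords-style tools.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError


@dataclass(frozen=True)
class Fragment:
    """Aligned fragment on the reference: 1-based inclusive interval."""

    start: int
    end: int
    identity: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def fragments_from_coords(coords: pd.DataFrame) -> list:
    return [
        Fragment(int(r.ref_start), int(r.ref_end), float(r.pct_identity))
        for r in coords.itertuples()
    ]


def _contained(a: Fragment, b: Fragment) -> bool:
    """True when a lies wholly inside b."""
    return b.start <= a.start and a.end <= b.end and (a.start, a.end) != (b.start, b.end)


def _overlap(a: Fragment, b: Fragment) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def merge_fragments(fragments, overlap_frac=0.10, frame="shorter") -> list:
    """Apply the containment filter and >10%-overlap join until fixpoint.

    ``frame`` selects the denominator of the 10% rule: the shorter fragment
    (default, the stricter reading) or the longer one.
    """
    if frame not in ("shorter", "longer"):
        raise ValueError("frame must be 'shorter' or 'longer'")
    frags = sorted(fragments, key=lambda f: (f.start, -(f.length)))
    changed = True
    while changed:
        changed = False
        # containment filter
        kept = []
        for f in frags:
            if any(_contained(f, g) for g in frags if g is not f):
                changed = True
            else:
                kept.append(f)
        # drop exact duplicates, keep first
        seen, frags = set(), []
        for f in kept:
            key = (f.start, f.end)
            if key in seen:
                changed = True
                continue
            seen.add(key)
            frags.append(f)
        # left-to-right join pass
        out = []
        for f in frags:
            if not out:
                out.append(f)
                continue
            g = out[-1]
            ov = _overlap(g, f)
            ref_len = min(g.length, f.length) if frame == "shorter" else max(g.length, f.length)
            if ov > overlap_frac * ref_len:
                ident = (g.length * g.identity + f.length * f.identity) / (g.length + f.length)
                out[-1] = Fragment(min(g.start, f.start), max(g.end, f.end), ident)
                changed = True
            else:
                out.append(f)
        frags = sorted(out, key=lambda f: (f.start, -(f.length)))
    return frags


def anib(fragments, merge=True, **merge_kw) -> float:
    """Size-weighted mean identity of the (merged) fragment set."""
    frags = merge_fragments(fragments, **merge_kw) if merge else list(fragments)
    if not frags:
        raise UndefinedStatisticError("ANIb undefined for an empty fragment set")
    lengths = np.array([f.length for f in frags], dtype=float)
    idents = np.array([f.identity for f in frags], dtype=float)
    return float((lengths * idents).sum() / lengths.sum())


def anib_matrix(coords_by_pair: dict, strains=None, **merge_kw) -> pd.DataFrame:
    """Symmetric ANIb matrix from per-ordered-pair coordinate tables.

    ``coords_by_pair`` maps (query, reference) to a CoordsTable frame; the
    value for an unordered pair is the mean of the directional values provided.
    Missing pairs are NaN, never zero.
    """
    if strains is None:
        strains = sorted({s for pair in coords_by_pair for s in pair})
    mat = pd.DataFrame(np.nan, index=strains, columns=strains, dtype=float)
    np.fill_diagonal(mat.values, 100.0)
    for a in strains:
        for b in strains:
            if a >= b:
                continue
            vals = []
            for pair in ((a, b), (b, a)):
                if pair in coords_by_pair:
                    vals.append(anib(fragments_from_coords(coords_by_pair[pair]), **merge_kw))
            if vals:
                mat.loc[a, b] = mat.loc[b, a] = float(np.mean(vals))
    return mat
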