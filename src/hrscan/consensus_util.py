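"""Interval arithmetic shared by consensus calling and truth matching."""
from __future__ import annotations


def reciprocal_overlap(a, b) -> float:
    """Overlap of two half-open intervals as a fraction of the *longer* one;
    >= 0.5 is the cross-method / truth-matching criterion."""
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    if ov == 0:
        return 0.0
    return ov / max(a[1] - a[0], b[1] - b[0])


def interval_union_length(intervals) -> int:
    """Total length of the union of half-open intervals."""
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    if cur_s is not None:
        total += cur_e - cur_s
    return total
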