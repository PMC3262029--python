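"""The no-zero TSS-relative coordinate axis.

Positions are integers with no zero: ``+1`` is the TSS base itself, ``-1``
the base immediately upstream, increasing in the direction of transcription.
A window ``-500..+500`` therefore spans exactly 1000 bases with the TSS at
0-based scan index 500.  ``linear`` maps the axis onto contiguous integers
(``+1 -> 0``, ``-1 -> -1``) so interval arithmetic stays ordinary.
"""

from __future__ import annotations

__all__ = ["linear", "unlinear", "rel_add", "window_length", "window_bins"]


def linear(rel: int) -> int:
    """Map a no-zero coordinate to a contiguous integer."""
    rel = int(rel)
    if rel == 0:
        raise ValueError("0 is not a valid TSS-relative coordinate")
    return rel - 1 if rel > 0 else rel


def unlinear(u: int) -> int:
    """Inverse of :func:`linear`."""
    u = int(u)
    return u + 1 if u >= 0 else u


def rel_add(rel: int, delta: int) -> int:
    """Advance a no-zero coordinate by ``delta`` bases."""
    return unlinear(linear(rel) + delta)


def window_length(upstream_rel: int | None, downstream_rel: int) -> int:
    """Length in bp of a window ``upstream_rel..downstream_rel``.

    ``upstream_rel`` is ``None`` (window starts at the TSS) or <= -1;
    ``downstream_rel`` >= +1.
    """
    if downstream_rel < 1:
        raise ValueError("downstream bound must be >= +1")
    if upstream_rel is None:
        return downstream_rel
    if upstream_rel > -1:
        raise ValueError("upstream bound must be <= -1 or None")
    return -upstream_rel + downstream_rel


def window_bins(window: tuple[int, int], bin_width: int) -> list[tuple[int, int]]:
    """Tile a TSS-relative window with bins anchored at the TSS.

    Downstream bins are ``[+1,+20], [+21,+40], ...`` and upstream bins
    ``[-20,-1], [-40,-21], ...`` (for ``bin_width`` 20); no bin straddles the
    TSS.  The outermost bins are clipped to the window bounds so the bins
    tile the window exactly.  Returned ascending.
    """
    lo, hi = window
    lo_u, hi_u = linear(lo), linear(hi)
    if lo_u > hi_u:
        raise ValueError("inverted window")
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    bins: list[tuple[int, int]] = []
    # upstream side (linear coords < 0)
    if lo_u < 0:
        top = min(hi_u, -1)
        b_hi = -1
        while b_hi >= lo_u:
            b_lo = b_hi - bin_width + 1
            bins.append((max(b_lo, lo_u), min(b_hi, top)))
            b_hi = b_lo - 1
        bins.reverse()
    # downstream side (linear coords >= 0)
    if hi_u >= 0:
        bot = max(lo_u, 0)
        b_lo = 0
        while b_lo <= hi_u:
            b_hi = b_lo + bin_width - 1
            bins.append((max(b_lo, bot), min(b_hi, hi_u)))
            b_lo = b_hi + 1
    return [(unlinear(a), unlinear(b)) for a, b in bins]
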