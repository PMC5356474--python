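"""Small runtime utilities."""

from __future__ import annotations

import ctypes
import logging

logger = logging.getLogger(__name__)

_M_TRIM_THRESHOLD = -1
_M_MMAP_THRESHOLD = -3
_tuned = False


def prefer_heap_allocations(threshold_bytes: int = 1 << 30) -> bool:
    """Keep large malloc blocks on the reusable process heap (glibc only).

    Genome-scale simulation allocates and frees many multi-megabyte arrays;
    by default glibc serves those via mmap, so every replicate pays full
    page-fault cost on first touch.  Raising the mmap and trim thresholds
    lets freed buffers be recycled, which speeds repeated simulation several
    fold.  No-op (returns False) on non-glibc platforms.
    """
    global _tuned
    if _tuned:
        return True
    try:
        libc = ctypes.CDLL("libc.so.6")
        ok = libc.mallopt(_M_MMAP_THRESHOLD, threshold_bytes) == 1
        ok = libc.mallopt(_M_TRIM_THRESHOLD, threshold_bytes) == 1 and ok
    except OSError:
        logger.debug("mallopt unavailable; allocator left at defaults")
        return False
    _tuned = ok
    return ok
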