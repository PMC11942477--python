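"""Process-level runtime tuning for CPU training.

Autodiff graphs allocate and free many multi-megabyte arrays per step;
with glibc's default malloc thresholds those arrays are mmap'ed and
returned to the kernel on free, so every step pays the page faults
again. Raising the mmap/trim thresholds keeps freed blocks on the heap
for reuse, which speeds training severalfold. A no-op on platforms
without glibc's ``mallopt``.
"""

from __future__ import annotations

import ctypes

_M_TRIM_THRESHOLD = -1
_M_MMAP_THRESHOLD = -3

_done = False


def tune_allocator() -> bool:
    """Raise glibc malloc thresholds so large autodiff arrays are reused."""
    global _done
    if _done:
        return True
    try:
        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(_M_MMAP_THRESHOLD, 1 << 30)
        libc.mallopt(_M_TRIM_THRESHOLD, (1 << 31) - 1)
        _done = True
    except OSError:
        return False
    return True
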