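"""flaseg: feature-location attention U-Net for FAZ segmentation."""

__version__ = "0.1.0"


def _tune_allocator() -> None:
    # Large temporaries (im2col patch matrices) otherwise hit glibc's mmap
    # path and the kernel re-zeroes fresh pages on every training step.
    import ctypes
    import sys
    if not sys.platform.startswith("linux"):
        return
    try:
        libc = ctypes.CDLL("libc.so.6", use_errno=True)
        libc.mallopt(ctypes.c_int(-3), ctypes.c_int(1 << 29))  # M_MMAP_THRESHOLD
    except Exception:
        pass


_tune_allocator()

from . import attention, losses, metrics, network, synthetic  # noqa: E402,F401
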