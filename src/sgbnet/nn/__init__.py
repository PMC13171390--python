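"""Compact numpy autodiff engine and neural-network building blocks."""

import ctypes as _ctypes


def _tune_allocator():
    """Keep large freed buffers on glibc's free list.

    Training allocates and frees multi-megabyte activation buffers every
    step; by default glibc hands those straight back to the kernel and
    re-requests (and re-zeroes) them on the next step.  Raising the trim
    and mmap thresholds lets the buffers be recycled in user space.
    """
    try:
        libc = _ctypes.CDLL("libc.so.6")
        libc.mallopt(-1, _ctypes.c_int(1 << 30))  # M_TRIM_THRESHOLD
        libc.mallopt(-3, _ctypes.c_int(1 << 30))  # M_MMAP_THRESHOLD
    except Exception:  # non-glibc platform: purely an optimisation
        pass


_tune_allocator()

from .autodiff import (
    Tensor,
    add,
    batch_norm2d,
    clip,
    concat,
    conv2d,
    global_avg_pool,
    global_max_pool,
    log,
    max_pool2,
    mean,
    mul,
    no_grad,
    power,
    relu,
    reshape,
    resize_bilinear,
    sigmoid,
    tensor_sum,
)
from .modules import (
    Adam,
    BatchNorm2d,
    Conv2d,
    Identity,
    Module,
    Parameter,
    Sequential,
    he_init,
)

__all__ = [
    "Tensor", "add", "batch_norm2d", "clip", "concat", "conv2d",
    "global_avg_pool", "global_max_pool", "log", "max_pool2", "mean", "mul",
    "no_grad", "power", "relu", "reshape", "resize_bilinear", "sigmoid",
    "tensor_sum", "Adam", "BatchNorm2d", "Conv2d", "Identity", "Module",
    "Parameter", "Sequential", "he_init",
]
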