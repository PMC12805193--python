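"""MILP backend helpers.

HiGHS (scipy's MILP backend) occasionally writes progress lines straight
to the process stdout; computations that call the solver thousands of
times would drown their own output, so solver calls run with file
descriptors 1/2 temporarily pointed at the null device.
"""

from __future__ import annotations

import contextlib
import os
import sys


@contextlib.contextmanager
def quiet_solver():
    try:
        sys.stdout.flush()
        sys.stderr.flush()
        saved = os.dup(1), os.dup(2)
    except (OSError, ValueError):  # non-standard streams; just run
        yield
        return
    devnull = os.open(os.devnull, os.O_WRONLY)
    try:
        os.dup2(devnull, 1)
        os.dup2(devnull, 2)
        yield
    finally:
        os.dup2(saved[0], 1)
        os.dup2(saved[1], 2)
        os.close(saved[0])
        os.close(saved[1])
        os.close(devnull)
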