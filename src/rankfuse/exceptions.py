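"""Exception hierarchy.

ValidationError: the input violates a structural contract (non-permutation
column, ragged file, bad simplex, ...).  CLI exit code 2.

CapabilityError: the input is structurally valid but exceeds what the exact
solvers can handle (problem size above the enumeration / branch-and-bound
ceiling).  Raised instead of silently falling back to a heuristic.  CLI exit
code 3.
"""


class RankfuseError(Exception):
    """Base class for all package errors."""


class ValidationError(RankfuseError, ValueError):
    """Input violates a structural invariant."""


class CapabilityError(RankfuseError, RuntimeError):
    """Problem size exceeds the exact-solver ceiling."""
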