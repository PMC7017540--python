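"""Exception hierarchy shared by all modules.

The CLI maps these onto exit codes: :class:`InputError` -> 2,
:class:`AlgorithmError` (and subclasses) -> 3.
"""


class GreedystackError(Exception):
    """Base class for all package errors."""


class InputError(GreedystackError, ValueError):
    """Invalid user input: malformed tables, mismatched lengths, bad options."""


class UndefinedMetricError(GreedystackError, ValueError):
    """A metric has no defined value on the given data.

    Examples: AUROC with a single observed class, Spearman correlation of a
    constant sequence.
    """


class AlgorithmError(GreedystackError, RuntimeError):
    """A fitting procedure failed (solver non-convergence, no valid candidate)."""


class ResourceError(GreedystackError, RuntimeError):
    """A requested computation exceeds a configured safety cap."""
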