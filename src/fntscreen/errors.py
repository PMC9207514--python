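"""Exception hierarchy for fntscreen.

Every error raised deliberately by the package derives from
:class:`FntScreenError`, so callers (and the CLI) can catch the package's
failures without swallowing programming errors.
"""


class FntScreenError(Exception):
    """Base class for all fntscreen errors."""


class InputError(FntScreenError, ValueError):
    """Malformed or inconsistent user input (shapes, labels, files)."""


class ConfigError(FntScreenError, ValueError):
    """Invalid configuration (bounds, arities, population sizes...)."""


class GenerationError(FntScreenError, RuntimeError):
    """Grammar-guided tree generation failed to produce a valid tree."""


class OptimizationError(FntScreenError, RuntimeError):
    """The swarm optimizer encountered a non-finite fitness value."""


class TrainingError(FntScreenError, ValueError):
    """Training data cannot support model fitting (e.g. single class)."""


class SelectionError(FntScreenError, ValueError):
    """Decoy pool cannot satisfy the requested negative-sample count."""


class FeaturizationError(FntScreenError, ValueError):
    """One or more compound records could not be featurized."""


class MetricError(FntScreenError, ValueError):
    """A metric is undefined for the given inputs (e.g. single-class AUC)."""
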