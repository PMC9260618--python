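"""Exception hierarchy.

All errors raised by the library derive from :class:`ColonyOptError` so that
callers can catch one base class; validation and configuration problems are
additionally ``ValueError`` subclasses for idiomatic use.
"""


class ColonyOptError(Exception):
    """Base class for all colonyopt errors."""


class ValidationError(ColonyOptError, ValueError):
    """An input value violates a model precondition (negative energy, eps > 1, ...)."""


class ConfigurationError(ColonyOptError, ValueError):
    """A configuration is structurally invalid (unknown utility family,
    non-increasing fitness map, non-concave family passed to the solver)."""


class ScenarioError(ColonyOptError, ValueError):
    """A scenario file failed schema validation.

    Carries *all* validation problems found, not just the first.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__(
            "scenario validation failed:\n" + "\n".join(f"  - {p}" for p in self.problems)
        )


class UndefinedQuantityError(ColonyOptError, ArithmeticError):
    """A requested quantity is mathematically undefined at this state
    (per-capita productivity of an empty colony, MRS with a saturated
    denominator task, reproductive ratio with zero queen offspring)."""


class DegenerateColonyError(ColonyOptError):
    """An operation would leave the colony without any worker caste."""
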