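"""Exception hierarchy."""


class MBEScreenError(Exception):
    """Base class for all package errors."""


class InputError(MBEScreenError):
    """Invalid or insufficient user input (empty structure, bad key, ...)."""


class FormatError(MBEScreenError):
    """A file did not parse under the named standard."""


class FragmentationError(MBEScreenError):
    """The fragmentation protocol could not be applied to the structure."""


class DependencyError(MBEScreenError):
    """A required subset energy is missing from the supplied energy map."""


class BackendError(MBEScreenError):
    """An energy backend failed to evaluate a geometry."""


class EvaluationError(MBEScreenError):
    """Energy assembly hit an unconverged or missing backend energy."""


class GenerationError(MBEScreenError):
    """Synthetic-fixture generation failed (e.g. packing infeasible)."""
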