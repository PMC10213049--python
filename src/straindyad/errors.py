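"""Exception types shared across the pipeline."""


class StrainDyadError(Exception):
    """Base class for all straindyad errors."""


class ParameterError(StrainDyadError, ValueError):
    """A simulation or analysis parameter is outside its valid range."""


class InputError(StrainDyadError, ValueError):
    """An input object violates a precondition (wrong length, type, labels)."""


class AlignmentError(StrainDyadError):
    """Two sequences could not be placed onto common coordinates."""


class UndefinedStatisticError(StrainDyadError):
    """A statistic is undefined for the given data (e.g. zero compared sites).

    Raised instead of returning 0 so an undefined ANI/popANI can never be
    confused with a maximally divergent one.
    """
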