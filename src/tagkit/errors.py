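"""Exception hierarchy for the in-silico cloning and design engine."""


class TagkitError(Exception):
    """Base class for all tagkit errors."""


class SequenceError(TagkitError):
    """Invalid nucleotide or protein sequence input."""


class UncutSequenceError(TagkitError):
    """A circular molecule has no site for the requested enzyme."""


class NonSpecificPrimingError(TagkitError):
    """A PCR primer binds zero times or more than once on the template."""


class NoProductError(TagkitError):
    """Primers anneal but face away from each other: no amplicon forms."""


class LigationError(TagkitError):
    """Fragment ends are not compatible for ligation."""


class InsufficientHomologyError(TagkitError):
    """SLIC terminal identity shorter than the required minimum overlap."""


class AmbiguousAssemblyError(TagkitError):
    """More than one valid SLIC assembly (both insert orientations fit)."""


class RecombinationError(TagkitError):
    """Cre/loxP excision impossible (site count or orientation wrong)."""


class TargetingError(TagkitError):
    """Homologous-recombination integration failed (arms missing,
    non-unique or in the wrong order)."""


class DesignError(TagkitError):
    """A construct-design stage could not produce a valid output."""
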