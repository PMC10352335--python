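"""Exception hierarchy for design-time failures.

Hard errors (bad inputs, violated preconditions) raise; recoverable
per-candidate problems are reported through return values instead.
"""


class HackDesignError(ValueError):
    """Base class for all package-specific errors."""


class GenomeError(HackDesignError):
    """Malformed genome input (bad alphabet, empty record, ...)."""


class DuplicateIdError(HackDesignError):
    """A contig, protein or gene identifier occurs more than once."""


class AnnotationError(HackDesignError):
    """GFF3 annotation inconsistent with the genome."""


class FlankError(HackDesignError):
    """A requested homology arm runs outside its contig."""


class AmbiguousSequenceError(HackDesignError):
    """A sequence destined for an oligo contains N bases."""


class DesignError(HackDesignError):
    """A cassette or primer cannot be built from the given parts."""


class PCRError(HackDesignError):
    """In-silico PCR failure."""


class NoAmpliconError(PCRError):
    """At least one primer has no annealing site on the template."""


class AmbiguousProductError(PCRError):
    """More than one product could form; sites are listed in the message."""
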