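"""Exception hierarchy shared across the package."""


class PalaeomitoError(Exception):
    """Base class for all package errors."""


class ParseError(PalaeomitoError):
    """A text record (FASTA/FASTQ/TSV/Newick/variant label) could not be parsed."""


class RangeError(PalaeomitoError):
    """A coordinate or interval falls outside the reference frame."""


class ConsistencyError(PalaeomitoError):
    """A variant's stated reference base disagrees with the genome it is applied to."""


class ConfigError(PalaeomitoError):
    """Invalid simulation or pipeline configuration."""


class EmptyAssemblyError(PalaeomitoError):
    """No reads aligned; a consensus cannot be built."""


class InsufficientDataError(PalaeomitoError):
    """A summary was requested from cells with zero denominator."""


class UndefinedEstimateError(PalaeomitoError):
    """A proportion estimate was requested with an empty denominator."""


class MissingTaxonError(PalaeomitoError):
    """A focal genome or outgroup label is absent from the provided set."""


class TreeError(PalaeomitoError):
    """Malformed haplogroup or phylogenetic tree (e.g. duplicate node names)."""


class ValidationError(PalaeomitoError):
    """An input matrix or container violates a structural invariant."""


class IntegrityError(PalaeomitoError):
    """A pipeline intermediate no longer matches its recorded checksum."""


class DependencyError(PalaeomitoError):
    """A pipeline stage's upstream output is missing."""
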