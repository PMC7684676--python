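"""Exception hierarchy.

All parser/model failures raise a subclass of :class:`VarProtDBError` so the
CLI can turn any library error into a one-line diagnostic and a nonzero exit.
"""


class VarProtDBError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(VarProtDBError):
    """A file violates its format contract (FASTA/VCF/GTF/TSV)."""


class CoordinateError(VarProtDBError):
    """An interval or position falls outside its sequence."""


class ModelError(VarProtDBError):
    """A gene model violates a structural invariant (e.g. overlapping CDS)."""


class ReferenceMismatchError(VarProtDBError):
    """VCF REF allele disagrees with the genome base at that position.

    The classic symptom of annotating against the wrong genome build
    (e.g. hg19 variants on an hg38 FASTA).
    """


class SubstitutionError(VarProtDBError):
    """Expected reference residue not found at the substitution position."""


class BuildError(VarProtDBError):
    """Database build cannot proceed (e.g. zero translatable transcripts)."""


class ConfigError(VarProtDBError):
    """A simulation/run configuration is invalid or infeasible."""
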