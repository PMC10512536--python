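"""Exception hierarchy shared across the toolkit."""


class OpsinkitError(Exception):
    """Base class for all toolkit errors."""


class DuplicateIdError(OpsinkitError):
    """A sequence file contains two records with the same id."""


class EmptySequenceError(OpsinkitError):
    """A sequence record has an empty sequence."""


class GeneModelError(OpsinkitError):
    """A gene model violates its structural invariants."""


class NewickParseError(OpsinkitError):
    """A Newick string could not be parsed."""


class UnrootedTreeError(OpsinkitError):
    """A rooted-only consumer received an unrooted (multifurcating-root) tree."""


class NotAlignableError(OpsinkitError):
    """A query could not be anchored to the reference frame."""


class PipelineError(OpsinkitError):
    """A pipeline stage failed; the stage name is carried in the message."""
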