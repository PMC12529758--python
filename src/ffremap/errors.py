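"""Exception hierarchy.

Everything raised on bad user input or bad data derives from
:class:`FfremapError`, so the CLI can catch one type and exit nonzero.
"""


class FfremapError(Exception):
    """Base class for all errors raised by ffremap."""


class TopologyError(FfremapError):
    """Malformed or structurally invalid included-topology (.itp) file."""


class UnsupportedDialectError(TopologyError):
    """ITP feature outside the supported single-molecule dialect
    (preprocessor directives, multiple moleculetype sections, ...)."""


class ElementError(FfremapError):
    """Atomic mass could not be resolved to a chemical element."""


class GroFormatError(FfremapError):
    """Malformed Gromos87 (.gro) coordinate file."""


class GraphError(FfremapError):
    """Molecular graph cannot be built (disconnected, no connectivity)."""


class NotIsomorphicError(FfremapError):
    """The two molecular graphs are not isomorphic."""


class MatchTimeout(FfremapError):
    """Optional wall-clock limit exceeded during isomorphism search."""


class ConstraintError(FfremapError):
    """Invalid or contradictory atom-name equivalence constraints."""


class MappingError(FfremapError):
    """Atom mapping violates its invariants (not a bijection, ...)."""


class MappingNotFoundError(MappingError):
    """No mapping file for the requested molecule in the mapping directory."""


class CompositionError(FfremapError):
    """System composition inconsistent with the coordinate file."""
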