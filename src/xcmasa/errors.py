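"""Exception hierarchy.

Validation problems (bad inputs, unsatisfiable preconditions) derive from
:class:`ValidationError`; file/format problems derive from :class:`FormatError`.
The CLI maps the former to exit status 1 and the latter, together with OS-level
I/O errors, to exit status 2.
"""


class XcmasaError(Exception):
    """Base class for all package errors."""


class ValidationError(XcmasaError):
    """A precondition on user-supplied values is violated."""


class FormatError(XcmasaError):
    """A file could not be parsed or has the wrong schema/version."""


class ParseError(FormatError):
    """PDB text could not be parsed."""


class LookupFailure(ValidationError):
    """A named residue/template does not exist."""


class UnsupportedMutation(ValidationError):
    """Alanine substitution requested on GLY/ALA or a residue without CB."""


class IncompleteSite(ValidationError):
    """An annotated catalytic residue is absent or lacks a usable fa atom."""


class AnnotationConflict(ValidationError):
    """Annotated residue type disagrees with the structure."""


class IncomparableTemplates(ValidationError):
    """Templates differ in size or residue-type sequence."""
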