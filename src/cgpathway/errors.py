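"""Exception hierarchy.

Errors are grouped so the command-line layer can map them onto distinct
exit statuses: input/usage problems, morph convergence failures, and
everything else.
"""


class CGPathwayError(Exception):
    """Base class for all package errors."""


class InputError(CGPathwayError):
    """Bad user input: unreadable files, invalid parameters, bad selections."""


class StructureFormatError(InputError):
    """File could not be parsed as PDB or mmCIF, or the model is missing."""


class EmptyStructureError(InputError):
    """A selection produced a structure with no residues."""


class PairingError(InputError):
    """No (or too few) residues could be matched between two structures."""


class GeometryError(InputError):
    """Degenerate geometry: fewer than 3 pairs, collinear point set, ..."""


class ParameterError(InputError):
    """A configuration value violates its documented invariant."""


class MutationError(InputError):
    """A mutation site is absent or of an unsupported residue type."""


class DegenerateEndpointsError(InputError):
    """Start and target conformations coincide where a distinction is needed."""


class EnergyEvaluationError(CGPathwayError):
    """Energy could not be evaluated (e.g. non-finite coordinate)."""


class MorphConvergenceError(CGPathwayError):
    """The steered relaxation failed to reach the target conformation."""

    def __init__(self, message: str, achieved_rmsd: float):
        super().__init__(message)
        self.achieved_rmsd = achieved_rmsd
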