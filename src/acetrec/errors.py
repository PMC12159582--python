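"""Exception hierarchy for the acetrec pipeline."""


class AcetrecError(Exception):
    """Base class for all acetrec errors."""


class InvalidParameterError(AcetrecError, ValueError):
    """A parameter violates its documented invariants."""


class NonWatertightMeshError(AcetrecError, ValueError):
    """An operation requiring a closed solid received an open mesh."""

    def __init__(self, name: str, detail: str = ""):
        msg = f"mesh '{name}' is not a closed (watertight) solid"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)
        self.mesh_name = name


class TopologyMismatchError(AcetrecError, ValueError):
    """Corresponded meshes do not share vertex/face topology."""


class CupNotFoundError(AcetrecError, ValueError):
    """No concave spherical (acetabular cup) region was detected."""


class DegenerateGeometryError(AcetrecError, ValueError):
    """Input geometry is degenerate (coplanar sphere-fit points, collinear rim...)."""


class StageError(AcetrecError, RuntimeError):
    """A pipeline stage failed; carries the stage label for batch reporting."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
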