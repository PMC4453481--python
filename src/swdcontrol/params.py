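"""Model parameters and flat key-value configuration I/O.

The cortico-thalamic mean-field model has four population variables
(PY, IN, TC, RE) whose dynamics are fixed by input offsets ``h_*``,
timescale factors ``tau1..tau4``, connection strengths ``C1..C9``, the
sigmoid steepness base ``epsilon`` and the linear thalamic activation
``s[x] = a*x + b``.  :data:`DEFAULT_PARAMETERS` is the published set for
this model family; ``h_tc`` is the bifurcation parameter and defaults to
the middle of the bistable window, where the background focus coexists
with the spike-wave limit cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path


@dataclass(frozen=True)
class ModelParameters:
    """Constants of the single-area cortico-thalamic model.

    ``h_py, h_in, h_tc, h_re`` are dimensionless input offsets,
    ``tau1..tau4`` timescale factors (1/s), ``C1..C9`` nonnegative
    intra-loop connection strengths, ``epsilon > 1`` the sigmoid
    steepness base, and ``a, b`` the slope and intercept of the linear
    activation used in the thalamic subsystem.
    """

    h_py: float = -0.35
    h_in: float = -3.4
    h_tc: float = -1.75
    h_re: float = -5.0
    tau1: float = 26.0
    tau2: float = 32.5
    tau3: float = 2.6
    tau4: float = 2.6
    C1: float = 1.8
    C2: float = 4.0
    C3: float = 1.5
    C4: float = 0.2
    C5: float = 10.5
    C6: float = 0.6
    C7: float = 3.0
    C8: float = 3.0
    C9: float = 1.0
    epsilon: float = 250000.0
    a: float = 2.8
    b: float = 0.5

    def __post_init__(self) -> None:
        for name in ("tau1", "tau2", "tau3", "tau4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.epsilon <= 1:
            raise ValueError(f"epsilon must be > 1, got {self.epsilon}")
        for i in range(1, 10):
            if getattr(self, f"C{i}") < 0:
                raise ValueError(f"C{i} must be >= 0")

    def with_(self, **overrides: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **overrides)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: Default parameter set; h_tc = -1.75 places the model in the bistable regime.
DEFAULT_PARAMETERS = ModelParameters()


def load_config(path: str | Path) -> dict[str, float]:
    """Parse a flat ``key = value`` text config.

    Lines starting with ``#`` and blank lines are ignored.  Values are
    parsed as floats; a non-numeric value raises ``ValueError`` naming
    the offending line.
    """
    out: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        try:
            out[key.strip()] = float(val.strip())
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric value {val.strip()!r}") from exc
    return out


def save_config(values: dict[str, float], path: str | Path) -> None:
    """Write a flat ``key = value`` config, one entry per line."""
    Path(path).write_text(
        "".join(f"{k} = {v!r}\n" for k, v in values.items())
    )


def parameters_from_config(path: str | Path, base: ModelParameters | None = None) -> ModelParameters:
    """Build a parameter set from a config file, overriding ``base``.

    Keys that are not ModelParameters fields (e.g. ``alpha``) are ignored
    here; they belong to other layers of the configuration.
    """
    base = base if base is not None else DEFAULT_PARAMETERS
    cfg = load_config(path)
    names = {f.name for f in fields(ModelParameters)}
    return base.with_(**{k: v for k, v in cfg.items() if k in names})
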