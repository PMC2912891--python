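"""Run configuration: every search, model, operator and stopping option.

All fields carry defaults, so a Nexus file without a ``phyloga`` settings
block runs out of the box.  The block grammar is ``begin phyloga;`` followed
by ``key = value;`` statements and ``end;`` — see ``docs/settings.md``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

__all__ = ["RunSettings", "SettingsError"]


class SettingsError(ValueError):
    pass


HEURISTICS = ("hc", "sa", "ga", "metaga")
MODELS = ("JC", "K2P", "HKY85", "TN93", "GTR")
SELECTION_SCHEMES = ("rank", "tournament", "replacement", "improve", "keepthebest")
CP_MODES = ("strict", "stochastic", "off")
CP_HANDLING = ("blind", "supervised")
START_TREES = ("nj", "lnj", "random", "user")
OPERATOR_MODES = ("fixed", "ordered", "random", "dynamic")
COOLING_SCHEDULES = ("linear", "geometric", "logarithmic", "adaptive", "staged")

TOPOLOGY_OPERATORS = ("NNI", "SPR", "TBR", "TXS", "STS")
PARAMETER_OPERATORS = (
    "branch_lengths",
    "internal_branch_lengths",
    "rate_matrix",
    "gamma_shape",
    "pinv",
    "partition_rates",
)


@dataclass
class RunSettings:
    # --- heuristic ---
    heuristic: str = "metaga"
    populations: int = 4            # P, metaGA only
    individuals: int = 4            # I per population (GA: single population size)
    selection_scheme: str = "improve"
    recombination_prob: float = 0.2   # intra-population
    hybridization_prob: float = 0.1   # inter-population, metaGA only
    cp_mode: str = "stochastic"
    cp_tolerance: float = 0.05        # tolerance t
    cp_handling: str = "blind"

    # --- simulated annealing ---
    cooling_schedule: str = "geometric"
    start_temperature: float = 0.0    # 0 -> calibrate from probe proposals
    cooling_factor: float = 0.95
    temperature_decrease_every: int = 10
    max_accept_prob: float = 1.0
    reheat_every: int = 0             # 0 disables reheating
    reheat_factor: float = 2.0

    # --- substitution model ---
    model: str = "HKY85"
    use_pinv: bool = False
    use_gamma: bool = False
    gamma_categories: int = 4

    # --- starting trees ---
    starting_tree: str = "lnj"
    lnj_p: float = 0.25
    random_branch_length_mean: float = 0.1
    user_tree_file: str = ""

    # --- operators ---
    operator_mode: str = "fixed"
    enabled_operators: list[str] = field(default_factory=lambda: ["NNI", "SPR", "branch_lengths"])
    operator_frequencies: list[float] = field(default_factory=list)  # empty -> equal
    operator_min_frequency: float = 0.02
    adapt_interval: int = 100

    # --- intra-step optimization ---
    optimize_every: int = 50          # accepted steps (HC/SA) or generations (GA/metaGA); 0 = never
    optimize_final: bool = True

    # --- stopping ---
    max_steps: int = 20000            # HC / SA
    max_generations: int = 2000       # GA / metaGA
    max_time_seconds: float = 0.0     # 0 disables
    stability_window: int = 0         # 0 disables likelihood-stability stop
    stability_epsilon: float = 1e-4
    mre_enabled: bool = True          # intra-replicate MRE stop (metaGA only)
    mre_interval: int = 5             # sample consensus every n > 1 generations
    mre_threshold: float = 0.05
    mre_consecutive: int = 10

    # --- replicates ---
    replicates: int = 1
    min_replicates: int = 0           # >0 enables auto inter-replicate MRE stop
    max_replicates: int = 0
    inter_mre_threshold: float = 0.05
    inter_mre_consecutive: int = 10

    # --- misc ---
    seed: int = 1
    workers: int = 1                  # performance knob only; never changes results
    lrt_alpha: float = 0.05

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def choice(value, options, name):
            if value not in options:
                raise SettingsError(f"{name} must be one of {options}, got {value!r}")

        choice(self.heuristic, HEURISTICS, "heuristic")
        choice(self.model, MODELS, "model")
        choice(self.selection_scheme, SELECTION_SCHEMES, "selection_scheme")
        choice(self.cp_mode, CP_MODES, "cp_mode")
        choice(self.cp_handling, CP_HANDLING, "cp_handling")
        choice(self.starting_tree, START_TREES, "starting_tree")
        choice(self.operator_mode, OPERATOR_MODES, "operator_mode")
        choice(self.cooling_schedule, COOLING_SCHEDULES, "cooling_schedule")
        if self.populations < 1:
            raise SettingsError("populations must be >= 1")
        if self.individuals < 1:
            raise SettingsError("individuals must be >= 1")
        if not 0.0 <= self.lnj_p <= 1.0:
            raise SettingsError("lnj_p must lie in [0, 1]")
        if not 0.0 <= self.cp_tolerance <= 1.0:
            raise SettingsError("cp_tolerance must lie in [0, 1]")
        if self.mre_interval < 2:
            raise SettingsError("mre_interval must be > 1")
        for op in self.enabled_operators:
            if op not in TOPOLOGY_OPERATORS + PARAMETER_OPERATORS:
                raise SettingsError(f"unknown operator {op!r}")
        if self.operator_frequencies and len(self.operator_frequencies) != len(self.enabled_operators):
            raise SettingsError("operator_frequencies must match enabled_operators")

    # ------------------------------------------------------------------ I/O

    def to_block(self) -> str:
        """Render the settings as a Nexus ``phyloga`` command block."""
        lines = ["begin phyloga;"]
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if isinstance(value, list):
                rendered = ",".join(str(v) for v in value) if value else "none"
            elif isinstance(value, bool):
                rendered = "true" if value else "false"
            else:
                rendered = str(value) if value != "" else "none"
            lines.append(f"    {f.name} = {rendered};")
        lines.append("end;")
        return "\n".join(lines)

    @classmethod
    def from_statements(cls, statements: dict[str, str]) -> "RunSettings":
        """Build settings from ``key = value`` statements (unknown keys rejected)."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict[str, object] = {}
        for key, raw in statements.items():
            key = key.lower()
            if key not in fields:
                raise SettingsError(f"unknown setting {key!r}")
            kwargs[key] = _parse_value(raw, fields[key])
        return cls(**kwargs)


def _parse_value(raw: str, f: dataclasses.Field):
    raw = raw.strip()
    if f.type in ("list[str]", "list[float]") or "list" in str(f.type):
        if raw.lower() == "none" or raw == "":
            return []
        parts = [p.strip() for p in raw.split(",") if p.strip()]
        if "float" in str(f.type):
            return [float(p) for p in parts]
        return parts
    if f.type == "bool":
        if raw.lower() in ("true", "yes", "1"):
            return True
        if raw.lower() in ("false", "no", "0"):
            return False
        raise SettingsError(f"boolean setting {f.name!r} got {raw!r}")
    if f.type == "int":
        return int(raw)
    if f.type == "float":
        return float(raw)
    if raw.lower() == "none":
        return ""
    return raw
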