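"""Forward-chaining rule engine for semantic labeling of audiometric records.

The engine executes an ordered base of declarative ``condition -> assertion``
rules over derived per-ear features, resolving the four inference dimensions
(type, severity, laterality, treatment) to a fixpoint.  Conditions are written
in a small expression language over named features (boolean connectives,
comparisons, set membership), so the shipped rule base lives in an editable
text file rather than in code.

The module also provides straight-line (non-engine) implementations of the
four classification steps; these serve as an independent oracle for the
engine in the test suite.

Default rule families
---------------------
* type: mixed when both conductive and sensorineural evidence are present in
  the same patient (in either ear); conductive / sensorineural when only one
  kind of evidence exists; a default-etiology rule assigns sensorineural to
  hearing loss without specific evidence; normal otherwise.
* severity: band of the worse (larger) ear PTA.
* laterality: bilateral when both ears show loss, unilateral otherwise.
* treatment: cochlear-implant evaluation for bilateral severe-to-profound
  sensorineural loss (candidacy only -- hearing-aid benefit is not measurable
  here); surgical evaluation for conductive or mixed loss; hearing aid for the
  remaining sensorineural losses; monitoring otherwise.  Hearing-aid and
  cochlear-implant cases are additionally flagged eligible for auditory
  rehabilitation in the inference trace.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

from .errors import AudiosemError, ConfigurationError, SequencingError
from .features import EarFeatures, FeatureConfig, PatientRecord, ear_profile
from .vocab import DIMENSIONS, DIMENSION_VOCAB, SEVERITIES

# ---------------------------------------------------------------------------
# condition expression language
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:"
    r"(?P<num>-?\d+(?:\.\d+)?)"
    r"|(?P<str>'[^']*')"
    r"|(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op>==|!=|<=|>=|<|>|\(|\)|\{|\}|,)"
    r")"
)

_KEYWORDS = {"and", "or", "not", "in", "true", "false"}


class RuleSyntaxError(ConfigurationError):
    pass


def _tokenize(text: str) -> List[Tuple[str, str]]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise RuleSyntaxError(f"cannot tokenize {text[pos:]!r} in condition {text!r}")
            break
        pos = m.end()
        if m.lastgroup == "num":
            tokens.append(("num", m.group("num")))
        elif m.lastgroup == "str":
            tokens.append(("str", m.group("str")[1:-1]))
        elif m.lastgroup == "name":
            word = m.group("name")
            tokens.append(("kw" if word in _KEYWORDS else "name", word))
        else:
            tokens.append(("op", m.group("op")))
    return tokens


class _Parser:
    """Recursive-descent parser compiling a condition to a closure on a context dict."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0
        self.names: set = set()

    def _peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None)

    def _next(self):
        tok = self._peek()
        self.i += 1
        return tok

    def _expect(self, kind, value=None):
        k, v = self._next()
        if k != kind or (value is not None and v != value):
            raise RuleSyntaxError(f"expected {value or kind} in condition {self.text!r}, got {v!r}")
        return v

    def parse(self) -> Callable:
        fn = self._or()
        if self.i != len(self.tokens):
            raise RuleSyntaxError(f"trailing tokens in condition {self.text!r}")
        return fn

    def _or(self):
        left = self._and()
        parts = [left]
        while self._peek() == ("kw", "or"):
            self._next()
            parts.append(self._and())
        if len(parts) == 1:
            return left
        return lambda ctx, parts=tuple(parts): any(p(ctx) for p in parts)

    def _and(self):
        left = self._not()
        parts = [left]
        while self._peek() == ("kw", "and"):
            self._next()
            parts.append(self._not())
        if len(parts) == 1:
            return left
        return lambda ctx, parts=tuple(parts): all(p(ctx) for p in parts)

    def _not(self):
        if self._peek() == ("kw", "not"):
            self._next()
            inner = self._not()
            return lambda ctx, inner=inner: not inner(ctx)
        return self._comparison()

    _CMP = {
        "==": lambda a, b: a == b,
        "!=": lambda a, b: a != b,
        "<=": lambda a, b: a <= b,
        ">=": lambda a, b: a >= b,
        "<": lambda a, b: a < b,
        ">": lambda a, b: a > b,
    }

    def _comparison(self):
        left = self._atom()
        kind, value = self._peek()
        if kind == "op" and value in self._CMP:
            self._next()
            right = self._atom()
            op = self._CMP[value]
            return lambda ctx, left=left, right=right, op=op: op(left(ctx), right(ctx))
        if (kind, value) == ("kw", "in"):
            self._next()
            members = self._set_literal()
            return lambda ctx, left=left, members=members: left(ctx) in members
        return left

    def _set_literal(self) -> frozenset:
        self._expect("op", "{")
        members = []
        while True:
            kind, value = self._next()
            if kind == "num":
                members.append(float(value))
            elif kind == "str":
                members.append(value)
            else:
                raise RuleSyntaxError(f"set literals hold constants only, in {self.text!r}")
            kind, value = self._next()
            if (kind, value) == ("op", "}"):
                return frozenset(members)
            if (kind, value) != ("op", ","):
                raise RuleSyntaxError(f"malformed set literal in {self.text!r}")

    def _atom(self):
        kind, value = self._next()
        if kind == "num":
            const = float(value)
            return lambda ctx, const=const: const
        if kind == "str":
            return lambda ctx, value=value: value
        if kind == "kw" and value in ("true", "false"):
            const = value == "true"
            return lambda ctx, const=const: const
        if kind == "name":
            self.names.add(value)
            return lambda ctx, value=value: ctx[value]
        if (kind, value) == ("op", "("):
            inner = self._or()
            self._expect("op", ")")
            return inner
        raise RuleSyntaxError(f"unexpected token {value!r} in condition {self.text!r}")


def compile_condition(text: str) -> Tuple[Callable, frozenset]:
    """Compile a condition expression; returns (predicate, referenced names)."""
    parser = _Parser(text)
    fn = parser.parse()
    return fn, frozenset(parser.names)


# ---------------------------------------------------------------------------
# rules and rule bases
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Rule:
    """One declarative inference rule.

    Lower ``priority`` fires first within a dimension; ``when`` is a condition
    expression over the named context features; ``assertion`` is the label
    asserted for ``dimension`` when the condition holds.
    """

    rule_id: str
    dimension: str
    priority: int
    when: str
    assertion: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise ConfigurationError(f"{self.rule_id}: unknown dimension {self.dimension!r}")
        if self.assertion not in DIMENSION_VOCAB[self.dimension]:
            raise ConfigurationError(
                f"{self.rule_id}: assertion {self.assertion!r} not in the "
                f"{self.dimension} vocabulary"
            )
        fn, names = compile_condition(self.when)
        object.__setattr__(self, "_fn", fn)
        object.__setattr__(self, "_names", names)

    def matches(self, ctx: Dict) -> bool:
        return bool(self._fn(ctx))


@dataclass(frozen=True)
class RuleBase:
    """An ordered collection of rules covering all four dimensions."""

    rules: Tuple[Rule, ...]
    version: str = "1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "rules", tuple(self.rules))
        ids = [r.rule_id for r in self.rules]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ConfigurationError(f"duplicate rule ids: {dupes}")
        for dim in DIMENSIONS:
            if not any(r.dimension == dim for r in self.rules):
                raise ConfigurationError(f"rule base has no rule for dimension {dim!r}")

    def by_dimension(self, dim: str) -> List[Rule]:
        subset = [r for r in self.rules if r.dimension == dim]
        order = {id(r): i for i, r in enumerate(self.rules)}
        return sorted(subset, key=lambda r: (r.priority, order[id(r)]))


# -- plain-text serialization (bit-exact round trip through the canonical form)


def save_rule_base(rules: RuleBase, path=None) -> str:
    lines = ["# audiosem rule base", f"version = {rules.version}", ""]
    for r in rules.rules:
        lines += [
            f"[rule {r.rule_id}]",
            f"dimension = {r.dimension}",
            f"priority = {r.priority}",
            f"when = {r.when}",
            f"assert = {r.assertion}",
        ]
        if r.description:
            lines.append(f"description = {r.description}")
        lines.append("")
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def load_rule_base(source) -> RuleBase:
    """Parse a rule base from a path or from rule-file text."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source
    version = "1"
    blocks: List[Dict[str, str]] = []
    current: Optional[Dict[str, str]] = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = re.fullmatch(r"\[rule\s+([A-Za-z0-9_.-]+)\]", line)
        if m:
            current = {"rule_id": m.group(1)}
            blocks.append(current)
            continue
        if "=" not in line:
            raise ConfigurationError(f"unparseable rule-file line: {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if current is None:
            if key == "version":
                version = val
                continue
            raise ConfigurationError(f"{key!r} outside any [rule] block")
        current[key] = val
    rules = []
    for b in blocks:
        try:
            rules.append(
                Rule(
                    rule_id=b["rule_id"],
                    dimension=b["dimension"],
                    priority=int(b["priority"]),
                    when=b["when"],
                    assertion=b["assert"],
                    description=b.get("description", ""),
                )
            )
        except KeyError as exc:
            raise ConfigurationError(f"rule {b.get('rule_id')}: missing field {exc}") from exc
    return RuleBase(rules=tuple(rules), version=version)


def default_rule_base(config: Optional[FeatureConfig] = None) -> RuleBase:
    """The shipped 18-rule base, with severity cutoffs taken from ``config``."""
    config = config or FeatureConfig()
    c1, c2, c3, c4 = config.severity_cutoffs
    rules = [
        Rule("type_mixed", "type", 10,
             "conductive_any and sensorineural_any", "mixed",
             "Both conductive and sensorineural characteristics detected in the same patient."),
        Rule("type_conductive", "type", 20,
             "conductive_any and not sensorineural_any", "conductive",
             "Conductive evidence (air-bone gap or abnormal tympanogram with loss) only."),
        Rule("type_sensorineural", "type", 30,
             "not conductive_any and (sensorineural_any or loss_any)", "sensorineural",
             "Sensorineural evidence, or hearing loss without specific evidence (default adult etiology)."),
        Rule("type_normal", "type", 40,
             "not conductive_any and not sensorineural_any and not loss_any", "normal",
             "No hearing loss and no pathological evidence in either ear."),
        Rule("severity_normal", "severity", 10,
             f"worse_pta <= {c1:g}", "normal", "Worse-ear PTA within normal limits."),
        Rule("severity_mild", "severity", 20,
             f"worse_pta > {c1:g} and worse_pta <= {c2:g}", "mild", "Mild band."),
        Rule("severity_moderate", "severity", 30,
             f"worse_pta > {c2:g} and worse_pta <= {c3:g}", "moderate", "Moderate band."),
        Rule("severity_severe", "severity", 40,
             f"worse_pta > {c3:g} and worse_pta <= {c4:g}", "severe", "Severe band."),
        Rule("severity_profound", "severity", 50,
             f"worse_pta > {c4:g}", "profound",
             f"Profound hearing loss when the pure-tone average exceeds {c4:g} dB HL."),
        Rule("laterality_bilateral", "laterality", 10,
             "left_has_loss and right_has_loss", "bilateral",
             "Both ears demonstrate hearing loss."),
        Rule("laterality_left", "laterality", 20,
             "left_has_loss and not right_has_loss", "unilateral_left", "Left ear only."),
        Rule("laterality_right", "laterality", 30,
             "right_has_loss and not left_has_loss", "unilateral_right", "Right ear only."),
        Rule("laterality_normal", "laterality", 40,
             "not left_has_loss and not right_has_loss", "normal", "Neither ear shows loss."),
        Rule("treat_cochlear_implant", "treatment", 10,
             "hl_type == 'sensorineural' and severity in {'severe', 'profound'} "
             "and laterality == 'bilateral'", "cochlear_implant_evaluation",
             "Cochlear implant candidacy for bilateral severe-to-profound sensorineural loss; "
             "the limited-hearing-aid-benefit clause is not measurable in these data."),
        Rule("treat_surgical", "treatment", 20,
             "hl_type in {'conductive', 'mixed'} and severity != 'normal'", "surgical_evaluation",
             "Conductive or mixed loss warrants surgical / otological evaluation."),
        Rule("treat_hearing_aid", "treatment", 30,
             "hl_type == 'sensorineural' and severity != 'normal' and "
             "not (severity in {'severe', 'profound'} and laterality == 'bilateral')",
             "hearing_aid",
             "Mild-to-moderate, or unilateral severe-to-profound, sensorineural loss."),
        Rule("treat_monitoring_normal", "treatment", 40,
             "hl_type == 'normal'", "monitoring", "Normal hearing: periodic monitoring."),
        Rule("treat_monitoring_default", "treatment", 50,
             "true", "monitoring",
             "Fallback for subclinical evidence without measurable loss."),
    ]
    return RuleBase(rules=tuple(rules))


def packaged_rule_base() -> RuleBase:
    """Load the rule base shipped as editable package data."""
    text = resources.files("audiosem").joinpath("data/default_rules.txt").read_text("utf-8")
    return load_rule_base(text)


# ---------------------------------------------------------------------------
# semantic labels and the engine
# ---------------------------------------------------------------------------

REHAB_TRACE_NOTE = "note:auditory_rehabilitation_eligible"

_DIM_VAR = {"type": "hl_type", "severity": "severity",
            "laterality": "laterality", "treatment": "treatment"}


@dataclass
class SemanticLabels:
    """The four inferred dimensions plus the ordered trace of fired rules."""

    hl_type: str
    severity: str
    laterality: str
    treatment: Optional[str] = None
    trace: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for dim, value in (("type", self.hl_type), ("severity", self.severity),
                           ("laterality", self.laterality)):
            if value not in DIMENSION_VOCAB[dim]:
                raise ConfigurationError(f"unknown {dim} label {value!r}")
        if self.treatment is not None and self.treatment not in DIMENSION_VOCAB["treatment"]:
            raise ConfigurationError(f"unknown treatment label {self.treatment!r}")


def build_context(left: EarFeatures, right: EarFeatures,
                  record: Optional[PatientRecord] = None) -> Dict:
    """Expose per-ear features (and optionally patient covariates) to rules."""
    ctx = {
        "left_pta": left.pta, "right_pta": right.pta,
        "worse_pta": max(left.pta, right.pta),
        "better_pta": min(left.pta, right.pta),
        "left_hf_pta": left.hf_pta, "right_hf_pta": right.hf_pta,
        "left_abg": left.abg if left.abg is not None else 0.0,
        "right_abg": right.abg if right.abg is not None else 0.0,
        "left_abg_known": left.abg is not None,
        "right_abg_known": right.abg is not None,
        "left_has_loss": left.has_loss, "right_has_loss": right.has_loss,
        "loss_any": left.has_loss or right.has_loss,
        "left_conductive_evidence": left.conductive_evidence,
        "right_conductive_evidence": right.conductive_evidence,
        "conductive_any": left.conductive_evidence or right.conductive_evidence,
        "left_sensorineural_evidence": left.sensorineural_evidence,
        "right_sensorineural_evidence": right.sensorineural_evidence,
        "sensorineural_any": left.sensorineural_evidence or right.sensorineural_evidence,
        "hl_type": "unset", "severity": "unset",
        "laterality": "unset", "treatment": "unset",
    }
    if record is not None:
        ctx["age"] = float(record.age)
        for flag in ("diabetes", "hypertension", "cardiovascular",
                     "noise_exposure", "smoking", "alcohol"):
            ctx[flag] = bool(getattr(record, flag))
    return ctx


def infer_labels(left: EarFeatures, right: EarFeatures, rules: RuleBase,
                 record: Optional[PatientRecord] = None) -> SemanticLabels:
    """Forward-chain ``rules`` over one patient's ear features to a fixpoint.

    Within each dimension rules are tried in priority order and the first
    match asserts the label; dimensions are revisited until all four are set
    or no further rule can fire.
    """
    ctx = build_context(left, right, record)
    by_dim = {dim: rules.by_dimension(dim) for dim in DIMENSIONS}
    labels: Dict[str, str] = {}
    trace: List[str] = []
    progressed = True
    while len(labels) < len(DIMENSIONS) and progressed:
        progressed = False
        for dim in DIMENSIONS:
            if dim in labels:
                continue
            for rule in by_dim[dim]:
                if rule.matches(ctx):
                    labels[dim] = rule.assertion
                    ctx[_DIM_VAR[dim]] = rule.assertion
                    trace.append(rule.rule_id)
                    progressed = True
                    break
    missing = [d for d in DIMENSIONS if d not in labels]
    if missing:
        raise AudiosemError(f"rule base failed to label dimension(s): {missing}")
    if labels["treatment"] in ("hearing_aid", "cochlear_implant_evaluation"):
        trace.append(REHAB_TRACE_NOTE)
    return SemanticLabels(
        hl_type=labels["type"], severity=labels["severity"],
        laterality=labels["laterality"], treatment=labels["treatment"],
        trace=trace,
    )


def apply_rule_base(record: PatientRecord, rules: RuleBase,
                    config: FeatureConfig) -> SemanticLabels:
    """Label one record: derive ear profiles, then run the engine.

    Mirrors the complete-case policy: a record with missing audiometric data
    raises :class:`MissingDataError` from the feature stage.
    """
    left = ear_profile(record, "left", config)
    right = ear_profile(record, "right", config)
    return infer_labels(left, right, rules, record)


# ---------------------------------------------------------------------------
# straight-line classifiers (the independent, non-engine formulation)
# ---------------------------------------------------------------------------


def classify_type(left: EarFeatures, right: EarFeatures) -> str:
    conductive = left.conductive_evidence or right.conductive_evidence
    sensorineural = left.sensorineural_evidence or right.sensorineural_evidence
    loss = left.has_loss or right.has_loss
    if conductive and sensorineural:
        return "mixed"
    if conductive:
        return "conductive"
    if sensorineural or loss:
        return "sensorineural"
    return "normal"


def classify_severity(left: EarFeatures, right: EarFeatures,
                      config: FeatureConfig) -> str:
    return config.severity_band(max(left.pta, right.pta))


def classify_laterality(left: EarFeatures, right: EarFeatures) -> str:
    if left.has_loss and right.has_loss:
        return "bilateral"
    if left.has_loss:
        return "unilateral_left"
    if right.has_loss:
        return "unilateral_right"
    return "normal"


def recommend_treatment(labels: SemanticLabels,
                        record: Optional[PatientRecord] = None) -> str:
    t, s, lat = labels.hl_type, labels.severity, labels.laterality
    if "unset" in (t, s, lat):
        raise SequencingError("type, severity and laterality must be inferred first")
    if t == "sensorineural" and s in ("severe", "profound") and lat == "bilateral":
        return "cochlear_implant_evaluation"
    if t in ("conductive", "mixed") and s != "normal":
        return "surgical_evaluation"
    if t == "sensorineural" and s != "normal":
        return "hearing_aid"
    return "monitoring"


def straight_line_labels(left: EarFeatures, right: EarFeatures,
                         config: FeatureConfig) -> SemanticLabels:
    """Compose the four straight-line classifiers (no rule engine involved)."""
    labels = SemanticLabels(
        hl_type=classify_type(left, right),
        severity=classify_severity(left, right, config),
        laterality=classify_laterality(left, right),
    )
    labels.treatment = recommend_treatment(labels)
    return labels


# ---------------------------------------------------------------------------
# rule-base validation (the consistency-checking stand-in)
# ---------------------------------------------------------------------------


@dataclass
class RuleValidationReport:
    """Outcome of the brute-force grid sweep over synthetic ear features."""

    n_points: int
    exhaustiveness_violations: List[Tuple[str, Dict]] = field(default_factory=list)
    exclusivity_violations: List[Tuple[str, Tuple[str, str], Dict]] = field(default_factory=list)
    unreachable_rules: List[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not (self.exhaustiveness_violations or self.exclusivity_violations)

    def summary(self) -> str:
        return (
            f"{self.n_points} grid points: "
            f"{len(self.exhaustiveness_violations)} exhaustiveness, "
            f"{len(self.exclusivity_violations)} exclusivity violations; "
            f"unreachable rules: {self.unreachable_rules or 'none'}"
        )


def validate_rule_base(rules: RuleBase, config: Optional[FeatureConfig] = None,
                       pta_step: int = 1, pta_max: int = 120) -> RuleValidationReport:
    """Sweep a synthetic grid of ear features and audit the rule base.

    The grid covers per-ear PTAs 0..``pta_max`` in ``pta_step`` dB steps
    crossed with every combination of the four evidence flags.  For every
    point and every dimension the report records: exhaustiveness (some rule
    matches), exclusivity (no two equal-priority rules assert different
    labels) and, across the sweep, rules that never fire first.

    Match results are memoized on the context features each dimension's rules
    actually reference, which keeps the exhaustive 1 dB sweep fast.
    """
    config = config or FeatureConfig()
    by_dim = {dim: rules.by_dimension(dim) for dim in DIMENSIONS}
    dim_names = {dim: frozenset().union(*(r._names for r in by_dim[dim])) if by_dim[dim] else frozenset()
                 for dim in DIMENSIONS}
    caches: Dict[str, Dict] = {dim: {} for dim in DIMENSIONS}
    fired: set = set()
    report = RuleValidationReport(n_points=0)

    ptas = list(range(0, pta_max + 1, pta_step))
    flag_grid = list(product((False, True), repeat=4))
    cutoff = config.hl_cutoff

    for lp in ptas:
        for rp in ptas:
            l_loss, r_loss = lp > cutoff, rp > cutoff
            for lc, ls, rc, rs in flag_grid:
                report.n_points += 1
                ctx = {
                    "left_pta": float(lp), "right_pta": float(rp),
                    "worse_pta": float(max(lp, rp)), "better_pta": float(min(lp, rp)),
                    "left_hf_pta": float(lp), "right_hf_pta": float(rp),
                    "left_abg": 0.0, "right_abg": 0.0,
                    "left_abg_known": False, "right_abg_known": False,
                    "left_has_loss": l_loss, "right_has_loss": r_loss,
                    "loss_any": l_loss or r_loss,
                    "left_conductive_evidence": lc, "right_conductive_evidence": rc,
                    "conductive_any": lc or rc,
                    "left_sensorineural_evidence": ls, "right_sensorineural_evidence": rs,
                    "sensorineural_any": ls or rs,
                    "hl_type": "unset", "severity": "unset",
                    "laterality": "unset", "treatment": "unset",
                }
                for dim in DIMENSIONS:
                    key = tuple(ctx.get(n) for n in sorted(dim_names[dim]))
                    hit = caches[dim].get(key)
                    if hit is None:
                        matches = [r for r in by_dim[dim] if r.matches(ctx)]
                        label = matches[0].assertion if matches else None
                        fired_id = matches[0].rule_id if matches else None
                        conflict = None
                        for a, b in zip(matches, matches[1:]):
                            if a.priority == b.priority and a.assertion != b.assertion:
                                conflict = (a.rule_id, b.rule_id)
                                break
                        hit = (label, fired_id, conflict)
                        caches[dim][key] = hit
                        sample = {"left_pta": lp, "right_pta": rp,
                                  "evidence": (lc, ls, rc, rs),
                                  "labels_so_far": {d: ctx[_DIM_VAR[d]] for d in DIMENSIONS}}
                        if label is None:
                            report.exhaustiveness_violations.append((dim, sample))
                        if conflict is not None:
                            report.exclusivity_violations.append((dim, conflict, sample))
                    label, fired_id, _ = hit
                    if fired_id is not None:
                        fired.add(fired_id)
                    ctx[_DIM_VAR[dim]] = label if label is not None else "unset"

    report.unreachable_rules = [r.rule_id for r in rules.rules if r.rule_id not in fired]
    return report
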