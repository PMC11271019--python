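"""Presence-and-type validation of chapter parameters.

Each report template ships with a JSON schema describing its input
parameters; a chapter's configuration must satisfy that schema before
anything renders. The validator covers the draft-07 keywords the
template schemas use — ``type``, ``required``, ``properties``,
``items``, ``enum``, ``additionalProperties``, ``minimum``/``maximum``
— and reports every failure with the parameter path, what was expected
and what was found, rather than stopping at the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ValidationFailure", "ValidationReport", "validate"]

_TYPES = {
    "string": (str,),
    "number": (int, float),
    "integer": (int,),
    "boolean": (bool,),
    "array": (list,),
    "object": (dict,),
    "null": (type(None),),
}


@dataclass
class ValidationFailure:
    parameter: str  # dotted path, "" for the document root
    message: str
    expected: str | None = None
    got: object = None

    def __str__(self) -> str:
        where = self.parameter or "<root>"
        return f"{where}: {self.message}"


@dataclass
class ValidationReport:
    failures: list[ValidationFailure] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.failures

    def __str__(self) -> str:
        if self.passed:
            return "parameters valid"
        return "; ".join(str(f) for f in self.failures)


def _type_ok(value, expected: str) -> bool:
    kinds = _TYPES.get(expected)
    if kinds is None:
        return True  # unknown type name: do not reject
    if expected in ("number", "integer") and isinstance(value, bool):
        return False  # bool is an int in Python, not in JSON
    if expected == "integer" and isinstance(value, float):
        return value.is_integer()
    return isinstance(value, kinds)


def _validate(value, schema: dict, path: str, out: list[ValidationFailure]) -> None:
    expected = schema.get("type")
    if expected is not None:
        types = expected if isinstance(expected, list) else [expected]
        if not any(_type_ok(value, t) for t in types):
            out.append(
                ValidationFailure(
                    path,
                    f"expected type {' or '.join(types)}, got {type(value).__name__} ({value!r})",
                    expected="/".join(types),
                    got=value,
                )
            )
            return  # structural keywords below assume the right type
    if "enum" in schema and value not in schema["enum"]:
        out.append(
            ValidationFailure(
                path, f"value {value!r} not one of {schema['enum']!r}",
                expected=repr(schema["enum"]), got=value,
            )
        )
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if "minimum" in schema and value < schema["minimum"]:
            out.append(
                ValidationFailure(path, f"{value} below minimum {schema['minimum']}")
            )
        if "maximum" in schema and value > schema["maximum"]:
            out.append(
                ValidationFailure(path, f"{value} above maximum {schema['maximum']}")
            )
    if isinstance(value, dict):
        for name in schema.get("required", []):
            if name not in value:
                out.append(
                    ValidationFailure(
                        f"{path}.{name}" if path else name,
                        "required parameter missing",
                        expected="present",
                    )
                )
        props = schema.get("properties", {})
        for name, sub in props.items():
            if name in value:
                _validate(value[name], sub, f"{path}.{name}" if path else name, out)
        if schema.get("additionalProperties") is False:
            for name in value:
                if name not in props:
                    out.append(
                        ValidationFailure(
                            f"{path}.{name}" if path else name,
                            "unknown parameter",
                        )
                    )
    if isinstance(value, list) and "items" in schema:
        for i, item in enumerate(value):
            _validate(item, schema["items"], f"{path}[{i}]", out)


def validate(params, schema: dict) -> ValidationReport:
    """Check *params* against *schema*; returns a report, never raises."""
    failures: list[ValidationFailure] = []
    _validate(params, schema, "", failures)
    return ValidationReport(failures)
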