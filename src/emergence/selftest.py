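"""Built-in exact verification suite for the parity toy systems.

Checks closed-form criterion values against table enumeration for all three
parity dynamics, so a broken build is caught without any sampling noise.
"""

from __future__ import annotations

from .criteria import evaluate
from .toys import (
    ParitySystemSpec,
    binary_entropy,
    joint_with_feature,
    state_names,
    supervenience_check,
)

_TOL = 1e-9


def run_selftest(echo=print) -> int:
    """Run the exact toy-system checks; returns the number of failures."""
    failures = 0

    def check(label: str, ok: bool) -> None:
        nonlocal failures
        echo(f"  [{'ok' if ok else 'FAIL'}] {label}")
        if not ok:
            failures += 1

    for n in (2, 3, 4):
        for g in (0.6, 0.9, 0.99):
            spec = ParitySystemSpec(n=n, gamma=g, variant="example1")
            joint = joint_with_feature(spec)
            past, future = state_names(n)
            r = evaluate(joint, feature_labels=("v", "v'"),
                         system_labels=(past, future))
            expected = 1 - binary_entropy(g)
            check(
                f"example1 n={n} gamma={g}: psi = 1 - H_b(gamma)",
                abs(r.psi - expected) < _TOL
                and abs(r.delta) < _TOL
                and abs(r.gamma) < _TOL,
            )
            dev = supervenience_check(joint, "v", past, future)
            check(
                f"example1 n={n} gamma={g}: parity is supervenient",
                abs(dev) < _TOL,
            )

    spec = ParitySystemSpec(n=3, variant="example2")
    joint = joint_with_feature(spec)
    past, future = state_names(3)
    r = evaluate(joint, feature_labels=("v", "v'"),
                 system_labels=(past, future))
    check("example2: delta = 1 bit (downward causation)",
          abs(r.delta - 1.0) < _TOL)
    check("example2: gamma = 1 bit", abs(r.gamma - 1.0) < _TOL)

    spec = ParitySystemSpec(n=3, gamma=0.9, variant="example3")
    joint = joint_with_feature(spec)
    r = evaluate(joint, feature_labels=("v", "v'"),
                 system_labels=(past, future))
    check("example3: psi > 0 and delta > 0 co-exist",
          r.psi > _TOL and r.delta > _TOL)

    return failures
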