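"""Prior-knowledge edge constraints for structure search.

Six rules restrict the causal orientations the search may consider:

1. No genomic feature (SNP, pathway score, ancestry component) can be
   influenced by a non-genomic feature.
2. Neuro-psychological test results cannot be influenced by neuro-imaging
   features (the reverse direction is allowed).
3. Age does not depend on any other variable.
4. The baseline diagnosis cannot be influenced by any clinical variable
   except age and education level (genomic parents remain allowed).
5. The education level does not depend on any other clinical variable.
6. The time-to-diagnosis does not influence any other variable, and it
   always depends on the censoring indicator (a one-edge whitelist).

Rule 2's direction is configurable (``imaging_to_neuropsych_forbidden``)
because the narrative around diagnosis-driven imaging changes admits the
opposite reading; the default forbids imaging -> neuropsych as stated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

#: roles treated as genomically derived
GENOMIC_ROLES = {"genomic", "pathway", "component"}
#: roles counted as clinical for rules 4 and 5
CLINICAL_ROLES = {"imaging", "neuropsych", "demographic", "age", "education", "diagnosis"}

VALID_ROLES = GENOMIC_ROLES | CLINICAL_ROLES | {"event_time", "censoring_flag"}


@dataclass
class ConstraintSet:
    forbidden: set[tuple[str, str]] = field(default_factory=set)
    required: set[tuple[str, str]] = field(default_factory=set)

    def allows(self, u: str, v: str) -> bool:
        return (u, v) not in self.forbidden

    def violations(self, edges) -> list[tuple[str, str]]:
        return [e for e in edges if e in self.forbidden]


def build_blacklist(
    roles: dict[str, str],
    imaging_to_neuropsych_forbidden: bool = True,
) -> ConstraintSet:
    """Expand the six role-level rules into a directed-edge blacklist.

    Every variable must carry a role from ``VALID_ROLES``. The censoring
    indicator -> event time arc is returned as the single required edge when
    both variables are present.
    """
    untagged = [v for v in roles if roles[v] not in VALID_ROLES]
    if untagged:
        raise ValueError(f"variables with missing/unknown roles: {untagged}")
    names = list(roles)
    forbidden: set[tuple[str, str]] = set()
    by_role: dict[str, list[str]] = {}
    for v, r in roles.items():
        by_role.setdefault(r, []).append(v)

    def forbid(src_roles: set[str], dst_roles: set[str]) -> None:
        for rs, rd in product(src_roles, dst_roles):
            for u in by_role.get(rs, []):
                for v in by_role.get(rd, []):
                    if u != v:
                        forbidden.add((u, v))

    all_roles = set(VALID_ROLES)
    # 1. non-genomic -> genomic forbidden
    forbid(all_roles - GENOMIC_ROLES, GENOMIC_ROLES)
    # 2. imaging -> neuropsych forbidden (direction configurable)
    if imaging_to_neuropsych_forbidden:
        forbid({"imaging"}, {"neuropsych"})
    else:
        forbid({"neuropsych"}, {"imaging"})
    # 3. nothing -> age
    forbid(all_roles - {"age"}, {"age"})
    # 4. clinical -> diagnosis forbidden except age and education
    forbid(CLINICAL_ROLES - {"age", "education", "diagnosis"}, {"diagnosis"})
    # 5. clinical -> education forbidden
    forbid(CLINICAL_ROLES - {"education"}, {"education"})
    # 6. event_time -> anything forbidden
    forbid({"event_time"}, all_roles)
    # self-loops always forbidden
    for v in names:
        forbidden.add((v, v))

    required: set[tuple[str, str]] = set()
    et = by_role.get("event_time", [])
    cf = by_role.get("censoring_flag", [])
    if len(et) > 1 or len(cf) > 1:
        raise ValueError("at most one event_time and one censoring_flag variable allowed")
    if et and cf:
        required.add((cf[0], et[0]))
        forbidden.discard((cf[0], et[0]))
    return ConstraintSet(forbidden=forbidden, required=required)
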