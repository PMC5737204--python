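import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def two_annotator_project():
    """Tiny two-annotator project with hand-placed entities/relations."""
    from annokit.model import Project, RelationType, RoundStatus, AnnotationSet
    from helpers import doc, ent, mrel

    d = doc("d1")
    jane_e = [
        ent("E1", (0, 10), "Chem", document=d, annotator="Jane"),
        ent("E2", (11, 21), "Dis", document=d, annotator="Jane"),
        ent("E3", (22, 32), "Chem", document=d, annotator="Jane"),
    ]
    jane_r = [mrel("R1", "Effect", ("E1", "E2"), annotator="Jane")]
    john_e = [
        ent("E1", (0, 10), "Chem", document=d, annotator="John"),
        ent("E2", (11, 21), "Dis", document=d, annotator="John"),
    ]
    john_r = [mrel("R1", "Effect", ("E1", "E2"), annotator="John")]
    project = Project(
        name="demo",
        documents={"d1": d},
        entity_types=[("Chem", "#111111"), ("Dis", "#222222")],
        relation_types=[RelationType("Effect"), RelationType("Hypothetical")],
        annotators=["Jane", "John"],
        rounds={1: RoundStatus.OPEN},
        round_meta={1: {}},
    )
    project.sets[("Jane", 1)] = AnnotationSet("Jane", 1, jane_e, jane_r)
    project.sets[("John", 1)] = AnnotationSet("John", 1, john_e, john_r)
    return project
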