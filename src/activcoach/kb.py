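"""RDF knowledge base: schema declaration and instance annotation.

The annotation schema links participants to their processed results through a
fixed set of object properties (health records, activity levels, step
predictions with interval days, weekly statistics, timestamped
recommendations) plus the sensing-side properties of the device/observation
vocabulary.  Instances are annotated as the pipeline produces them and the
whole graph serializes to Turtle; a serialized document parses back to an
identical triple count.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

from rdflib import RDF, RDFS, Graph, Literal, Namespace, URIRef
from rdflib.namespace import OWL, XSD

from .errors import SchemaError
from .intervals import PredictionInterval
from .weekly import WeeklySummary

AC = Namespace("https://w3id.org/activity-coach#")

#: object property -> (domain class(es), range class)
OBJECT_PROPERTIES: dict[str, tuple[tuple[str, ...], str]] = {
    "HasPersonalHealthRecord": (("Participant",), "HealthRecord"),
    "HasPersonalDataInfo": (("Participant",), "PersonalData"),
    "HasPersonalPreferences": (("Participant",), "Preferences"),
    "HasReceivedPersonalRecommendation": (("Participant",), "Recommendation"),
    "HasHealthStatus": (("Participant",), "ParticipantStatus"),
    "HasbeenCollectedBy": (("ActivityData",), "ActivityDataValue"),
    "HasTimeStamp": (("ActivityDataValue", "Questionnaire", "Recommendation",
                      "ParticipantHealthRecord"), "TemporalEntity"),
    "HasMeasurementCapability": (("ActivityDevice",), "MeasurementCapability"),
    "HasOutput": (("ActivityDevice",), "SensorOutput"),
    "Observes": (("ActivityDevice",), "Property"),
    "Detects": (("ActivityDevice",), "Stimulus"),
    "FeatureOfInterest": (("Observation",), "FeatureOfInterest"),
    "ObservationResult": (("Observation",), "SensorOutput"),
    "ObservedBy": (("Observation",), "Sensor"),
    "IsPropertyOf": (("Property",), "FeatureOfInterest"),
    "HasProperty": (("FeatureOfInterest",), "Property"),
    "HasIntervalDay": (("Participant",), "StepPrediction"),
    "HasActivityLevel": (("Participant",), "ActivityLevelDaily"),
    "HasStatValue": (("Participant",), "Statistical"),
}


class KnowledgeBase:
    """A populated RDF graph of schema + participant annotations."""

    def __init__(self) -> None:
        self.graph = Graph()
        self.graph.bind("ac", AC)
        self._declare_schema()
        self._recommendation_count = 0

    # -- schema -------------------------------------------------------------

    def _declare_schema(self) -> None:
        classes = {"Participant", "Recommendation", "TemporalEntity"}
        for domains, rng in OBJECT_PROPERTIES.values():
            classes.update(domains)
            classes.add(rng)
        for cls in sorted(classes):
            self.graph.add((AC[cls], RDF.type, OWL.Class))
        for prop, (domains, rng) in OBJECT_PROPERTIES.items():
            p = AC[prop]
            self.graph.add((p, RDF.type, OWL.ObjectProperty))
            for d in domains:
                self.graph.add((p, RDFS.domain, AC[d]))
            self.graph.add((p, RDFS.range, AC[rng]))

    def _check_property(self, prop: str) -> URIRef:
        if prop not in OBJECT_PROPERTIES:
            raise SchemaError(f"object property {prop!r} is not declared")
        return AC[prop]

    # -- instances ----------------------------------------------------------

    def add_participant(self, participant: str) -> URIRef:
        node = AC[f"participant/{participant}"]
        self.graph.add((node, RDF.type, AC.Participant))
        record = AC[f"participant/{participant}/health-record"]
        self.graph.add((record, RDF.type, AC.HealthRecord))
        self.graph.add((node, self._check_property("HasPersonalHealthRecord"),
                        record))
        return node

    def annotate_level(self, participant: str, date: dt.date,
                       level: int) -> None:
        node = AC[f"participant/{participant}/level/{date.isoformat()}"]
        self.graph.add((node, RDF.type, AC.ActivityLevelDaily))
        self.graph.add((node, AC.levelCode,
                        Literal(int(level), datatype=XSD.integer)))
        self.graph.add((node, AC.onDate, Literal(date, datatype=XSD.date)))
        self.graph.add((AC[f"participant/{participant}"],
                        self._check_property("HasActivityLevel"), node))

    def annotate_prediction(self, participant: str, week_id: int,
                            intervals: list[PredictionInterval]) -> None:
        for iv in intervals:
            node = AC[f"participant/{participant}/prediction/"
                      f"week-{week_id}/day-{iv.h}"]
            self.graph.add((node, RDF.type, AC.StepPrediction))
            self.graph.add((node, AC.pointForecast, Literal(iv.point)))
            self.graph.add((node, AC.lowerBound, Literal(iv.lower)))
            self.graph.add((node, AC.upperBound, Literal(iv.upper)))
            self.graph.add((AC[f"participant/{participant}"],
                            self._check_property("HasIntervalDay"), node))

    def annotate_stats(self, participant: str,
                       summary: WeeklySummary) -> None:
        node = AC[f"participant/{participant}/stats/week-{summary.week_id}"]
        self.graph.add((node, RDF.type, AC.Statistical))
        self.graph.add((node, AC.similarityScore, Literal(summary.sc)))
        self.graph.add((node, AC.performanceScore, Literal(summary.s_total)))
        self.graph.add((node, AC.meanScore, Literal(summary.mean_s)))
        self.graph.add((node, AC.deviation, Literal(summary.sd)))
        self.graph.add((AC[f"participant/{participant}"],
                        self._check_property("HasStatValue"), node))

    def annotate_recommendation(self, participant: str, date: dt.date,
                                variable_id: str, text: str) -> None:
        self._recommendation_count += 1
        node = AC[f"participant/{participant}/recommendation/"
                  f"{date.isoformat()}/{variable_id}"]
        self.graph.add((node, RDF.type, AC.Recommendation))
        self.graph.add((node, AC.variableId, Literal(variable_id)))
        self.graph.add((node, AC.messageText, Literal(text)))
        stamp = AC[f"time/{date.isoformat()}"]
        self.graph.add((stamp, RDF.type, AC.TemporalEntity))
        self.graph.add((node, self._check_property("HasTimeStamp"), stamp))
        self.graph.add((AC[f"participant/{participant}"],
                        self._check_property(
                            "HasReceivedPersonalRecommendation"), node))

    # -- queries and export -------------------------------------------------

    def recommendation_ids(self, participant: str) -> list[str]:
        """Fired message ids for a participant, via graph query."""
        q = """
        SELECT ?vid WHERE {
            ?p ac:HasReceivedPersonalRecommendation ?rec .
            ?rec ac:variableId ?vid .
        }"""
        node = AC[f"participant/{participant}"]
        return sorted(str(row.vid) for row in self.graph.query(
            q, initBindings={"p": node}, initNs={"ac": AC}))

    @property
    def n_recommendations(self) -> int:
        return self._recommendation_count

    def export_turtle(self, path: str | Path | None = None) -> str:
        doc = self.graph.serialize(format="turtle")
        if path is not None:
            Path(path).write_text(doc)
        return doc

    def __len__(self) -> int:
        return len(self.graph)


def parse_turtle(document: str) -> Graph:
    g = Graph()
    g.parse(data=document, format="turtle")
    return g
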