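"""Scenario classification summary for both simulated datasets.

Reads the scenario calls written by the pipeline stage and prints the final
verdicts with their rationale — the expected outcome is that the
independent-acquisitions dataset is called `multiple_independent_acquisitions`
(non-monophyly, four transitions) and the codiversification dataset
`single_acquisition_codiversification` (monophyly, full host congruence).
"""

import json
from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for name in ("independent", "codiversification"):
        path = RESULTS / f"pipeline_{name}" / "scenario_call.json"
        call = json.loads(path.read_text())
        print(f"[{name}] call = {call['call']}")
        print(f"    monophyly={call['monophyly_of_bgc_symbionts']} "
              f"transitions={call['fitch_transitions']} "
              f"congruence={call['host_symbiont_congruence']} "
              f"erosion_dispersion={call['erosion_dispersion']}")
        for why in call["rationale"]:
            print(f"    - {why}")


if __name__ == "__main__":
    main()
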