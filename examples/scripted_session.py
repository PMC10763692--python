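"""Drive the interactive console loop with scripted input.

The session asks all ten questions in order, rejects the invalid token
"maybe" once and re-asks the same question, then prints the score block.
The transcript records every consumed line for audit.
"""

import io

from naranjo import build_naranjo_scale, run_session

scale = build_naranjo_scale()
script = ["Y", "maybe", "Y", "N", "X", "N", "X", "X", "X", "Y", "Y"]

stdin = io.StringIO("".join(line + "\n" for line in script))
stdout = io.StringIO()
transcript = run_session(scale, stdin, stdout, case_id="demo")

print(stdout.getvalue())
print("transcript events:")
for event in transcript.events:
    print(f"  Q{event.question_index}: {event.raw!r} -> {event.outcome.value}")

# One 'rejected' event at question 2 shows the re-prompt loop; the final
# Assessment equals scoring the ten accepted answers.
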