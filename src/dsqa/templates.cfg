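# Answer-generation templates, one per question type: QType<TAB>template.
# Slots in {braces} are filled from the knowledge base at render time.
AdverseEffects	The {DS} has Adverse Effects like {objects}
Availability	Maybe you can find the information here: {link1} or {link2}
Background	{background}
Effectiveness	{DS} is effective for {objects}
Indication	{DS} is effective for {objects}
Interaction	{DS} interacts with {objects}
Safety	Here is what I found about {DS}: {safety}
Usage	This might help: {link1} or {link2}
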