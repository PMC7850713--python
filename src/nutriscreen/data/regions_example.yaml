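# Example country -> region grouping for multi-country reporting.
# Six geographic categories; the Democratic Republic of Congo stands as
# its own category, as is common when one country dominates the survey
# collection.  Edit freely — the grouping is configuration, not code.
Afghanistan: South Asia
Bangladesh: South Asia
Burkina Faso: West and Central Africa
Central African Republic: West and Central Africa
Chad: West and Central Africa
DRC: DRC
Guinea: West and Central Africa
Haiti: Latin America and Caribbean
India: South Asia
Kenya: East and South Africa
Madagascar: East and South Africa
Mali: West and Central Africa
Myanmar: East Asia and Pacific
Nepal: South Asia
Niger: West and Central Africa
Nigeria: West and Central Africa
Pakistan: South Asia
Philippines: East Asia and Pacific
Sierra Leone: West and Central Africa
Somalia: East and South Africa
South Sudan: East and South Africa
Sudan: East and South Africa
Uganda: East and South Africa
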