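# Starter bilingual NCD lexicon.
#
# Schema: category -> list of entries {label, en: [terms...], th: [terms...]}.
# Labels are canonical and unique within a category. English terms are matched
# as contiguous token subsequences after normalisation; Thai terms are matched
# as substrings of the raw comment text. Covers the four major NCD groups
# (cardiovascular disease, cancer, chronic respiratory disease, diabetes)
# plus hypertension and kidney disease; users supply their own file to extend.
disease:
  - label: cancer
    en: [cancer, tumor, tumour, carcinoma, leukemia, lymphoma, melanoma]
    th: [มะเร็ง, เนื้องอก]
  - label: heart disease
    en: [heart disease, heart attack, cardiovascular disease, heart failure, coronary]
    th: [โรคหัวใจ, หัวใจวาย, หัวใจล้มเหลว]
  - label: diabetes
    en: [diabetes, diabetic, blood sugar disease]
    th: [เบาหวาน]
  - label: chronic respiratory disease
    en: [copd, emphysema, asthma, chronic bronchitis, respiratory disease]
    th: [ถุงลมโป่งพอง, หอบหืด, โรคปอด]
  - label: hypertension
    en: [hypertension, high blood pressure]
    th: [ความดันโลหิตสูง, ความดัน]
  - label: kidney disease
    en: [kidney disease, renal failure, kidney failure]
    th: [โรคไต, ไตวาย]
symptom:
  - label: fatigue
    en: [fatigue, tired, exhausted, exhaustion, weakness]
    th: [เหนื่อย, อ่อนเพลีย, เหนื่อยง่าย]
  - label: chest pain
    en: [chest pain, chest tightness]
    th: [เจ็บหน้าอก]
  - label: cough
    en: [cough, coughing]
    th: [ไอเรื้อรัง]
  - label: shortness of breath
    en: [shortness of breath, breathless, short of breath]
    th: [หายใจลำบาก]
  - label: weight loss
    en: [weight loss, losing weight, lost weight]
    th: [น้ำหนักลด]
  - label: dizziness
    en: [dizzy, dizziness, lightheaded]
    th: [เวียนหัว]
  - label: headache
    en: [headache, headaches]
    th: [ปวดหัว]
  - label: numbness
    en: [numb, numbness, tingling]
    th: [ชา]
treatment:
  - label: chemotherapy
    en: [chemotherapy, chemo]
    th: [คีโม, เคมีบำบัด]
  - label: radiation therapy
    en: [radiation, radiotherapy]
    th: [ฉายแสง]
  - label: surgery
    en: [surgery, operation, surgical]
    th: [ผ่าตัด]
  - label: insulin
    en: [insulin]
    th: [อินซูลิน]
  - label: medication
    en: [medication, medicine, pills, drug]
    th: [กินยา]
  - label: dialysis
    en: [dialysis]
    th: [ฟอกไต]
behavior_cause:
  - label: smoking
    en: [smoking, smoke, smoker, cigarettes, cigarette]
    th: [สูบบุหรี่, บุหรี่]
  - label: alcohol
    en: [alcohol, drinking, drinker]
    th: [เหล้า, ดื่มเหล้า]
  - label: diet
    en: [diet, sugary food, junk food, fast food, sweets]
    th: [ของหวาน, น้ำตาล]
  - label: exercise
    en: [exercise, exercising, sedentary]
    th: [ออกกำลังกาย]
  - label: obesity
    en: [obesity, obese, overweight]
    th: [อ้วน]
  - label: stress
    en: [stress, stressed]
    th: [ความเครียด]
  - label: air pollution
    en: [air pollution, pollution, smog]
    th: [ฝุ่น, มลพิษ]
gender_cue:
  - label: male
    en: [he, him, his, father, dad, grandfather, uncle, brother, husband, son]
# "ตา" (grandfather) is omitted: as a substring it collides with common
# words like "ติดตาม", which would mis-assign gender.
    th: [ผม, พ่อ, ปู่, ลุง, ผู้ชาย]
  - label: female
    en: [she, her, hers, mother, mom, grandmother, aunt, sister, wife, daughter]
    th: [ฉัน, ดิฉัน, แม่, ย่า, ยาย, ป้า, ผู้หญิง]
source_cue:
  - label: self
    en: [i, me, my own, myself, i was diagnosed]
    th: [ผมเป็น, ฉันเป็น, ดิฉันเป็น, ตัวเอง]
  - label: family_member
    en: [my mother, my father, my mom, my dad, my sister, my brother, my wife,
         my husband, my son, my daughter, my grandmother, my grandfather,
         my aunt, my uncle, my family]
    th: [แม่ของ, พ่อของ, แม่ผม, พ่อผม, แม่ฉัน, พ่อฉัน, ครอบครัว, ยายของ, ปู่ของ]
  - label: acquaintance
    en: [my friend, my neighbor, my neighbour, my colleague, my coworker, a friend]
    th: [เพื่อนของ, เพื่อนผม, เพื่อนฉัน]
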