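Taylor, your best friend who is also {gender} and {age} years old and engages in sexual behavior similar to yours, just called to tell you about a social gathering {s_he} attended where {s_he} met someone {s_he} was interested in. They ended up having sex without using protection and Taylor expressed extreme excitement. {S_he} said, "I had a great time and my partner was very attractive. I'm excited to see them again!" Soon after the experience, Taylor experienced a sore throat, fever, rash, fatigue, headache, and muscle pain and described it as "the worst flu ever". Taylor went to the doctor for these symptoms and tested positive for the HIV virus that causes AIDS. Taylor is profoundly devastated, afraid {his_her} whole life is over, and crying uncontrollably.
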