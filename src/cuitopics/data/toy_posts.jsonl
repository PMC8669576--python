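{"id": "toy-01", "source": "forumA", "text": "I had my implants removed after years of back pain and fatigue #explant"}
{"id": "toy-02", "source": "forumA", "text": "The swelling and inflammation started 3 months after surgery 😭"}
{"id": "toy-03", "source": "forumA", "text": "My doctor said the pain was not related but the fatigue got worse https://example.org/story"}
{"id": "toy-04", "source": "forumA", "text": "Diagnosed with breast cancer in 2018, then an infection after the removal"}
{"id": "toy-05", "source": "forumB", "text": "Anxiety and exhaustion every single day @support it is real"}
{"id": "toy-06", "source": "forumB", "text": "Implant removal was the best decision, the inflammation is gone now!"}
{"id": "toy-07", "source": "forumB", "text": "Still dealing with back pain, swelling, and anxiety after 2 surgeries"}
{"id": "toy-08", "source": "forumB", "text": "Took ibuprofen for the pain but the swelling would not go down"}
{"id": "toy-09", "source": "forumC", "text": "My sister had breast carcinoma and we worry the implants made it worse #BII"}
{"id": "toy-10", "source": "forumC", "text": "Exhausted all the time, fatigue, brain fog, and joint pain since the implants"}
{"id": "toy-11", "source": "forumC", "text": "After the implant removal my anxiety finally eased and the infection healed"}
{"id": "toy-12", "source": "forumC", "text": "No symptoms here, just sharing support and love for everyone 💕"}
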