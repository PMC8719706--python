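{
  "name": "HEART",
  "response_min": 1,
  "response_max": 6,
  "subscales": [
    {
      "code": "TV",
      "name": "Traditional Values",
      "risk_direction": "none",
      "n_items": 13,
      "items": [
        {
          "id": "tv_01",
          "polarity": "normal",
          "text": "A man should have the final say in all family matters"
        },
        {
          "id": "tv_02",
          "polarity": "normal",
          "text": "I think there is nothing a woman can do if her husband wants to have girlfriends"
        },
        {
          "id": "tv_03",
          "polarity": "normal"
        },
        {
          "id": "tv_04",
          "polarity": "normal"
        },
        {
          "id": "tv_05",
          "polarity": "normal"
        },
        {
          "id": "tv_06",
          "polarity": "normal"
        },
        {
          "id": "tv_07",
          "polarity": "normal"
        },
        {
          "id": "tv_08",
          "polarity": "normal"
        },
        {
          "id": "tv_09",
          "polarity": "normal"
        },
        {
          "id": "tv_10",
          "polarity": "normal"
        },
        {
          "id": "tv_11",
          "polarity": "normal"
        },
        {
          "id": "tv_12",
          "polarity": "normal"
        },
        {
          "id": "tv_13",
          "polarity": "normal"
        }
      ]
    },
    {
      "code": "PS",
      "name": "Partner Support",
      "risk_direction": "low_is_risk",
      "n_items": 10,
      "items": [
        {
          "id": "ps_01",
          "polarity": "normal",
          "text": "My partner is as committed as I am to our relationship"
        },
        {
          "id": "ps_02",
          "polarity": "reversed",
          "text": "My partner does what he wants, even if I do not want him to"
        },
        {
          "id": "ps_03",
          "polarity": "normal"
        },
        {
          "id": "ps_04",
          "polarity": "normal"
        },
        {
          "id": "ps_05",
          "polarity": "normal"
        },
        {
          "id": "ps_06",
          "polarity": "normal"
        },
        {
          "id": "ps_07",
          "polarity": "normal"
        },
        {
          "id": "ps_08",
          "polarity": "normal"
        },
        {
          "id": "ps_09",
          "polarity": "normal"
        },
        {
          "id": "ps_10",
          "polarity": "normal"
        }
      ]
    },
    {
      "code": "PAC",
      "name": "Partner Abuse & Control",
      "risk_direction": "high_is_risk",
      "n_items": 9,
      "items": [
        {
          "id": "pac_01",
          "polarity": "normal",
          "text": "My partner makes fun of me or humiliates me"
        },
        {
          "id": "pac_02",
          "polarity": "normal",
          "text": "My partner slaps, hits, kicks, or pushes me"
        },
        {
          "id": "pac_03",
          "polarity": "normal",
          "text": "I can't seem to make good decisions about my life"
        },
        {
          "id": "pac_04",
          "polarity": "normal"
        },
        {
          "id": "pac_05",
          "polarity": "normal"
        },
        {
          "id": "pac_06",
          "polarity": "normal"
        },
        {
          "id": "pac_07",
          "polarity": "normal"
        },
        {
          "id": "pac_08",
          "polarity": "normal"
        },
        {
          "id": "pac_09",
          "polarity": "normal"
        }
      ]
    },
    {
      "code": "PR",
      "name": "Partner Resistance to HIV Prevention",
      "risk_direction": "high_is_risk",
      "n_items": 5,
      "items": [
        {
          "id": "pr_01",
          "polarity": "normal",
          "text": "If I asked my partner to use a condom, he would get angry"
        },
        {
          "id": "pr_02",
          "polarity": "normal"
        },
        {
          "id": "pr_03",
          "polarity": "normal"
        },
        {
          "id": "pr_04",
          "polarity": "normal"
        },
        {
          "id": "pr_05",
          "polarity": "normal"
        }
      ]
    },
    {
      "code": "HPR",
      "name": "HIV Prevention Readiness",
      "risk_direction": "none",
      "n_items": 5,
      "items": [
        {
          "id": "hpr_01",
          "polarity": "normal",
          "text": "Using an HIV prevention product shows that my partner and I care about each other"
        },
        {
          "id": "hpr_02",
          "polarity": "normal"
        },
        {
          "id": "hpr_03",
          "polarity": "normal"
        },
        {
          "id": "hpr_04",
          "polarity": "normal"
        },
        {
          "id": "hpr_05",
          "polarity": "normal"
        }
      ]
    }
  ]
}
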